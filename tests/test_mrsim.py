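import numpy as np
import pytest
from hypothesis import given, strategies as st

from trabspec import (
    AnalysisConfig,
    BinaryVolume,
    FrequencyBand,
    band_harmonics,
    collapse,
    integrated_band_power,
    mean_spectrum,
    sample_k_values,
    spectrum,
    subdivide_prisms,
    tile_vois,
)
from trabspec.mrsim import VOI, Prism
from trabspec.synthetic_bone import GrfBoneParams, generate_grf_bone


def ones_volume(shape, voxel=0.02):
    return BinaryVolume(np.ones(shape, dtype=bool), voxel)


class TestTiling:
    def test_single_voi(self):
        vois = tile_vois(ones_volume((250, 250, 250)), 5.0)
        assert len(vois) == 1
        assert vois[0].edge_vox == (250, 250, 250)

    def test_two_vois(self):
        vois = tile_vois(ones_volume((500, 250, 250)), 5.0)
        assert len(vois) == 2

    def test_mask_excludes_corner(self):
        vol = ones_volume((100, 100, 100))
        mask = np.ones((100, 100, 100), dtype=bool)
        mask[:50, :50, :50] = False  # knock out one corner octant
        vois = tile_vois(vol, 1.0, region_mask=mask)  # 50-voxel VOIs
        assert len(vois) == 7

    def test_no_fit_error(self):
        with pytest.raises(ValueError, match="no .* VOI fits"):
            tile_vois(ones_volume((10, 10, 10)), 5.0)


class TestPrisms:
    def test_25_prisms_per_5mm_voi(self):
        voi = VOI("v", (0, 0, 0), (250, 250, 250), 0)
        prisms = subdivide_prisms(voi, 1.0, 0.02)
        assert len(prisms) == 25

    def test_single_prism(self):
        voi = VOI("v", (0, 0, 0), (250, 250, 250), 0)
        assert len(subdivide_prisms(voi, 5.0, 0.02)) == 1

    def test_partition_exact(self):
        """Prism voxel sets are pairwise disjoint and union to the VOI."""
        voi = VOI("v", (10, 20, 30), (100, 100, 100), 1)
        prisms = subdivide_prisms(voi, 0.5, 0.02)  # 25-voxel cross
        assert len(prisms) == 16
        cover = np.zeros((120, 130, 140), dtype=int)
        for p in prisms:
            cover[p.slices()] += 1
        assert cover.max() == 1
        assert cover.sum() == 100**3
        assert cover[voi.slices()].all()

    def test_non_divisible_rejected(self):
        voi = VOI("v", (0, 0, 0), (250, 250, 250), 0)
        with pytest.raises(ValueError, match="not divisible"):
            subdivide_prisms(voi, 1.2, 0.02)


class TestCollapse:
    def test_all_bone_is_constant_one(self):
        prism = Prism("v", (0, 0, 0), (10, 10), 50, 0)
        signal = collapse(ones_volume((50, 10, 10)), prism)
        np.testing.assert_array_equal(signal, np.ones(50))

    def test_unit_cross_section_is_raw_line(self):
        rng = np.random.default_rng(0)
        voxels = rng.random((32, 4, 4)) < 0.5
        vol = BinaryVolume(voxels, 0.02)
        prism = Prism("v", (0, 1, 2), (1, 1), 32, 0)
        np.testing.assert_array_equal(
            collapse(vol, prism), voxels[:, 1, 2].astype(float)
        )

    def test_out_of_bounds_rejected(self):
        prism = Prism("v", (0, 0, 0), (10, 10), 60, 0)
        with pytest.raises(ValueError, match="exceeds"):
            collapse(ones_volume((50, 10, 10)), prism)


class TestSpectrum:
    def test_pure_cosine_single_harmonic(self):
        """A cosine with exactly 5 periods puts amplitude/2 at harmonic 5 and
        nothing anywhere else (machine precision)."""
        n, amp = 500, 0.8
        x = np.arange(n)
        signal = 1.0 + amp * np.cos(2 * np.pi * 5 * x / n)
        spec = spectrum(signal, 0.01)
        assert spec.magnitude[4] == pytest.approx(amp / 2, abs=1e-12)
        others = np.delete(spec.magnitude, 4)
        assert np.abs(others).max() < 1e-12

    def test_constant_signal_all_zero(self):
        spec = spectrum(np.full(64, 3.3), 0.01)
        assert np.abs(spec.magnitude).max() < 1e-12

    def test_frequency_grid(self):
        spec = spectrum(np.arange(100, dtype=float), 0.05)
        np.testing.assert_allclose(
            spec.frequency_per_mm, np.arange(1, 51) / (100 * 0.05)
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spectrum(np.ones(3), 0.01)

    @given(seed=st.integers(0, 30), n=st.sampled_from([64, 101, 250, 500]))
    def test_parseval(self, seed, n):
        """Two-sided reconstruction of the 1/N-normalised one-sided spectrum
        carries the full mean-square power of the mean-removed signal."""
        rng = np.random.default_rng(seed)
        signal = rng.random(n)
        spec = spectrum(signal, 0.01)
        mags2 = spec.magnitude**2
        if n % 2 == 0:
            power = 2 * mags2[:-1].sum() + mags2[-1]  # Nyquist counted once
        else:
            power = 2 * mags2.sum()
        expected = np.mean((signal - signal.mean()) ** 2)
        assert power == pytest.approx(expected, rel=1e-10)

    def test_translation_invariance(self, plate_phantom):
        """Shifting a periodic structure changes phases only; magnitudes are
        untouched — the spectral analogue of motion immunity."""
        prism = Prism("p", (0, 0, 0), (20, 20), 500, 0)
        signal = collapse(plate_phantom, prism)
        ref = spectrum(signal, 0.01)
        for shift in (1, 37, 250):
            shifted = spectrum(np.roll(signal, shift), 0.01)
            np.testing.assert_allclose(shifted.magnitude, ref.magnitude, atol=1e-12)


class TestMeanSpectrum:
    def _spec(self, mags):
        from trabspec.mrsim import Spectrum1D

        n = 2 * len(mags)
        idx = np.arange(1, len(mags) + 1)
        return Spectrum1D(idx, idx / (n * 0.01), np.asarray(mags, float), n, 0.01)

    def test_identical_spectra(self):
        s = self._spec([1.0, 2.0, 3.0])
        out = mean_spectrum([s, s, s])
        np.testing.assert_array_equal(out.magnitude, s.magnitude)

    def test_pointwise_mean(self):
        a = self._spec([0.0, 0.0, 0.0])
        b = self._spec([2.0, 4.0, 6.0])
        np.testing.assert_array_equal(mean_spectrum([a, b]).magnitude, [1.0, 2.0, 3.0])

    def test_mismatched_grids_rejected(self):
        a = self._spec([1.0, 2.0])
        b = self._spec([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="mismatched"):
            mean_spectrum([a, b])

    def test_phantom_prisms_identical(self, plate_phantom):
        """A translation-invariant phantom gives the same spectrum in every
        prism, so the mean equals any single one."""
        voi = VOI("p", (0, 0, 0), (500, 20, 20), 0)
        prisms = subdivide_prisms(voi, 0.1, 0.01)
        from trabspec.mrsim import prism_spectra

        spectra = prism_spectra(plate_phantom, prisms)
        assert len(spectra) == 4
        mean = mean_spectrum(spectra)
        np.testing.assert_allclose(mean.magnitude, spectra[0].magnitude, atol=1e-12)


class TestBandBookkeeping:
    @pytest.mark.parametrize(
        "band, expected",
        [
            (FrequencyBand(1.0, 1.8), np.arange(5, 10)),  # 5 points
            (FrequencyBand(3.8, 7.4), np.arange(19, 38)),  # 19 points
            (FrequencyBand(3.8, 5.6), np.arange(19, 29)),  # 10 points
        ],
    )
    def test_harmonic_resolution_at_5mm(self, band, expected):
        np.testing.assert_array_equal(band_harmonics(band, 5.0), expected)

    def test_counts_stable_for_near_nominal_window(self):
        """A 5 mm window realised as 555 voxels of 9 um still samples the
        printed point counts because membership is resolved in nominal-
        length harmonic space."""
        rng = np.random.default_rng(0)
        spec = spectrum(rng.random(555), 0.009)
        bands = [FrequencyBand(1.0, 1.8), FrequencyBand(3.8, 7.4)]
        samples = sample_k_values(spec, bands, 5.0)
        assert [len(s) for s in samples] == [5, 19]

    def test_band_beyond_spectrum_rejected(self):
        spec = spectrum(np.random.default_rng(1).random(16), 0.01)
        with pytest.raises(ValueError, match="stops at"):
            sample_k_values(spec, [FrequencyBand(3.8, 7.4)], 5.0)


class TestIntegratedBandPower:
    def test_phantom_power_independent_of_cross_section(self, plate_phantom):
        cfg = AnalysisConfig()
        voi = VOI("p", (0, 0, 0), (500, 20, 20), 0)
        table = integrated_band_power(
            plate_phantom, voi, cfg, cross_sizes_mm=[0.1, 0.2]
        )
        low = table[table.band == "low"].total_magnitude.to_numpy()
        np.testing.assert_allclose(low[0], low[1], rtol=1e-12)

    def test_grf_power_larger_for_narrow_cross_section(self):
        """Averaging over a wide cross-section washes structure out, so the
        in-band magnitude is higher for narrow prisms."""
        cfg = AnalysisConfig(
            voi_edge_mm=2.5, prism_cross_mm=0.5, nominal_analysis_length_mm=2.5
        )
        diffs = []
        for seed in range(4):
            vol = generate_grf_bone(
                GrfBoneParams(volume_shape_vox=(128, 128, 128), rng_seed=seed)
            )
            voi = tile_vois(vol, 2.5)[0]
            table = integrated_band_power(vol, voi, cfg, cross_sizes_mm=[0.5, 2.5])
            high = table[table.band == "high"].set_index("cross_mm").total_magnitude
            diffs.append(high[0.5] - high[2.5])
        assert np.mean(diffs) > 0

    def test_phantom_power_nondecreasing_with_length(self, plate_phantom):
        cfg = AnalysisConfig()
        voi = VOI("p", (0, 0, 0), (500, 20, 20), 0)
        table = integrated_band_power(
            plate_phantom,
            voi,
            cfg,
            # integer period counts (no leakage) at lengths where the
            # nominal-index band edges stay inside the true bands
            analysis_lengths_mm=[3.0, 5.0],
            cross_sizes_mm=[0.2],
        )
        for band in ("low", "high"):
            sub = table[table.band == band].set_index("analysis_length_mm")
            assert (
                sub.total_magnitude[5.0] >= sub.total_magnitude[3.0] - 1e-12
            )
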