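import numpy as np
import pytest
from scipy import optimize

from trabspec import (
    apply_classifier,
    cross_section_sweep,
    fit_boundary,
    predict,
    repeated_cv,
    tile_vois,
)
from trabspec.classify_eval import FittedBoundary
from trabspec.preprocess import disease_pipeline
from trabspec.synthetic_bone import CohortParams, generate_cohort


def hinge_boundary_oracle(values, labels, C=1.0):
    """Independent optimiser for the 1D soft-margin SVM objective
    0.5 w^2 + C * sum(max(0, 1 - y (w z + b))) on the z-scored feature,
    minimised from many starts; returns the boundary in metric units."""
    values = np.asarray(values, float)
    y = np.where(np.asarray(labels, bool), 1.0, -1.0)
    mu, sd = values.mean(), values.std()
    z = (values - mu) / sd

    def objective(p):
        w, b = p
        return 0.5 * w * w + C * np.maximum(0.0, 1.0 - y * (w * z + b)).sum()

    best = None
    for w0 in (-10, -3, -1, -0.3, 0.3, 1, 3, 10):
        for b0 in (-2, 0, 2):
            res = optimize.minimize(
                objective, [w0, b0], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            if best is None or res.fun < best.fun:
                best = res
    w, b = best.x
    return mu + sd * (-b / w), w > 0


class TestFitBoundary:
    def test_midpoint_of_two_points(self):
        fb = fit_boundary([0.0, 1.0], [False, True])
        assert fb.threshold == pytest.approx(0.5, abs=1e-6)
        assert fb.diseased_above

    def test_separable_training_rates_perfect(self):
        rng = np.random.default_rng(0)
        healthy = rng.normal(0.0, 0.1, 20)
        diseased = rng.normal(5.0, 0.1, 20)
        values = np.r_[healthy, diseased]
        labels = np.r_[np.zeros(20), np.ones(20)].astype(bool)
        fb = fit_boundary(values, labels)
        pred, (sens, spec) = apply_classifier(fb, values, labels)
        assert sens == 1.0 and spec == 1.0

    def test_matches_bruteforce_hinge_oracle(self):
        """On non-separable 1D data the fitted threshold agrees with an
        independent multi-start optimisation of the same hinge objective."""
        rng = np.random.default_rng(42)
        for trial in range(3):
            values = np.r_[rng.normal(0, 1, 25), rng.normal(1.2, 1, 25)]
            labels = np.r_[np.zeros(25), np.ones(25)].astype(bool)
            fb = fit_boundary(values, labels)
            threshold, above = hinge_boundary_oracle(values, labels)
            assert above == fb.diseased_above
            assert fb.threshold == pytest.approx(threshold, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_boundary([1.0, 2.0], [True, True])

    def test_identical_values_degenerate(self):
        fb = fit_boundary([1.0] * 10, [False] * 5 + [True] * 5)
        assert not predict(fb, [1.0]).any()  # everything healthy


class TestPredict:
    def test_tie_at_boundary_goes_healthy(self):
        fb = FittedBoundary(threshold=0.5, diseased_above=True)
        np.testing.assert_array_equal(
            predict(fb, [0.4, 0.5, 0.6]), [False, False, True]
        )
        fb_below = FittedBoundary(threshold=0.5, diseased_above=False)
        np.testing.assert_array_equal(
            predict(fb_below, [0.4, 0.5, 0.6]), [True, False, False]
        )

    def test_all_diseased_side_sensitivity_one(self):
        fb = FittedBoundary(threshold=0.0, diseased_above=True)
        pred, (sens, _) = apply_classifier(fb, [1.0, 2.0, 3.0], [True, True, True])
        assert sens == 1.0

    def test_boundary_shift_trades_specificity_for_sensitivity(self):
        """Moving the threshold into the healthy class monotonically raises
        sensitivity and lowers specificity — the tunable false-negative
        trade-off."""
        rng = np.random.default_rng(1)
        values = np.r_[rng.normal(1.0, 0.3, 50), rng.normal(0.0, 0.3, 50)]
        labels = np.r_[np.zeros(50), np.ones(50)].astype(bool)  # diseased below
        sens_list, spec_list = [], []
        for threshold in np.linspace(-0.5, 1.5, 9):  # sweep toward healthy
            fb = FittedBoundary(threshold=threshold, diseased_above=False)
            _, (sens, spec) = apply_classifier(fb, values, labels)
            sens_list.append(sens)
            spec_list.append(spec)
        assert all(a <= b + 1e-12 for a, b in zip(sens_list, sens_list[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec_list, spec_list[1:]))


class TestRepeatedCV:
    def test_chance_level_on_exchangeable_labels(self):
        """With labels carrying no information, mean sensitivity and
        specificity sit near 0.5 and sum to ~1."""
        rng = np.random.default_rng(3)
        values = rng.normal(size=200)
        labels = np.r_[np.zeros(100), np.ones(100)].astype(bool)
        report = repeated_cv(values, labels, folds=5, repeats=50, seed=2)
        assert 0.4 <= report.sensitivity_mean <= 0.6
        assert 0.4 <= report.specificity_mean <= 0.6
        assert report.sensitivity_mean + report.specificity_mean == pytest.approx(
            1.0, abs=0.15
        )

    def test_well_separated_classes_perfect(self):
        rng = np.random.default_rng(4)
        values = np.r_[rng.normal(0, 0.1, 30), rng.normal(1.0, 0.1, 30)]
        labels = np.r_[np.zeros(30), np.ones(30)].astype(bool)
        report = repeated_cv(values, labels, folds=5, repeats=10, seed=0)
        assert report.sensitivity_mean == 1.0 and report.sensitivity_sd == 0.0
        assert report.specificity_mean == 1.0 and report.specificity_sd == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        values = np.r_[rng.normal(0, 1, 20), rng.normal(1, 1, 20)]
        labels = np.r_[np.zeros(20), np.ones(20)].astype(bool)
        a = repeated_cv(values, labels, repeats=5, seed=7)
        b = repeated_cv(values, labels, repeats=5, seed=7)
        assert a == b
        c = repeated_cv(values, labels, repeats=5, seed=8)
        assert a != c

    def test_small_class_rejected(self):
        values = np.arange(8.0)
        labels = np.array([False] * 5 + [True] * 3)
        with pytest.raises(ValueError, match="stratification"):
            repeated_cv(values, labels, folds=5)

    def test_degradation_with_overlap(self):
        """Accuracy decays monotonically as the class separation shrinks."""
        rng = np.random.default_rng(6)
        accs = []
        base = rng.normal(0, 1, 40)
        noise = rng.normal(0, 1, 40)
        for gap in (3.0, 1.5, 0.5):
            values = np.r_[base, noise + gap]
            labels = np.r_[np.zeros(40), np.ones(40)].astype(bool)
            r = repeated_cv(values, labels, repeats=10, seed=1)
            accs.append(0.5 * (r.sensitivity_mean + r.specificity_mean))
        assert accs[0] > accs[1] > accs[2]


class TestCrossSectionSweep:
    @pytest.fixture(scope="class")
    def sweep_pairs(self):
        params = CohortParams(
            n_volumes=8,
            volume_shape_vox=(125, 125, 125),
            voxel_size_mm=0.04,
            rng_seed=17,
        )
        pairs = []
        for vol in generate_cohort(params):
            voi = tile_vois(vol, 5.0)[0]
            pairs.append((vol, disease_pipeline(vol, 1), voi))
        return pairs

    def test_m25_equals_standard_pipeline(self, sweep_pairs, default_config):
        from trabspec import repeated_cv, voi_ratio_metric

        table = cross_section_sweep(
            sweep_pairs, default_config, m_values=[25], seed=9
        )
        values, labels = [], []
        for healthy, diseased, voi in sweep_pairs:
            values.append(voi_ratio_metric(healthy, voi, default_config).metric)
            labels.append(False)
        for healthy, diseased, voi in sweep_pairs:
            values.append(voi_ratio_metric(diseased, voi, default_config).metric)
            labels.append(True)
        report = repeated_cv(values, labels, folds=5, repeats=50, seed=9)
        assert table.loc[0, "sensitivity_mean"] == pytest.approx(
            report.sensitivity_mean
        )
        assert table.loc[0, "specificity_mean"] == pytest.approx(
            report.specificity_mean
        )

    def test_fewer_prisms_never_beat_full_voi(self, sweep_pairs, default_config):
        table = cross_section_sweep(
            sweep_pairs, default_config, m_values=[1, 25], seed=9
        )
        acc = table.set_index("m_prisms")["accuracy_mean"]
        assert acc[1] <= acc[25]

    def test_deterministic(self, sweep_pairs, default_config):
        a = cross_section_sweep(sweep_pairs, default_config, m_values=[5], seed=3)
        b = cross_section_sweep(sweep_pairs, default_config, m_values=[5], seed=3)
        assert a.equals(b)

    def test_bad_m_rejected(self, sweep_pairs, default_config):
        with pytest.raises(ValueError, match="outside"):
            cross_section_sweep(sweep_pairs, default_config, m_values=[26])
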