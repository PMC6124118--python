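"""Thresholding, despeckling and morphological erosion.

These are the image-conditioning operators applied to micro-CT-like volumes
before texture analysis, plus the erosion operator used to simulate
osteopenic/osteoporotic bone loss: removing layers of voxels from every free
bone surface thins trabeculae and widens the gaps between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes_io import BinaryVolume, VolumeImage

logger = logging.getLogger("trabspec")

__all__ = [
    "DespeckleSpec",
    "otsu_threshold",
    "otsu_threshold_1d",
    "despeckle",
    "erode",
    "disease_pipeline",
]


@dataclass(frozen=True)
class DespeckleSpec:
    """Size threshold and connectivities for speckle removal.

    Connectivity values follow scipy.ndimage.generate_binary_structure:
    3 = 26-neighbourhood, 1 = 6-neighbourhood.  The complementary default
    pair (26 for bone, 6 for void) avoids topological paradoxes.
    """

    min_component_vox: int = 125
    foreground_connectivity: int = 3
    background_connectivity: int = 1

    def __post_init__(self) -> None:
        if self.min_component_vox < 1:
            raise ValueError("min_component_vox must be >= 1")
        for name in ("foreground_connectivity", "background_connectivity"):
            if getattr(self, name) not in (1, 2, 3):
                raise ValueError(f"{name} must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# Otsu thresholding


def _otsu_1d_threshold(values: np.ndarray) -> float:
    """Between-class-variance-maximising threshold over the unique values.

    Returns a threshold t; the foreground is values > t (t itself is the
    largest value of the background class).
    """
    levels, counts = np.unique(values.ravel(), return_counts=True)
    if levels.size < 2:
        raise ValueError("constant image: Otsu thresholding needs >= 2 distinct values")
    p = counts / counts.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    # candidates: split after each level except the last
    omega0 = omega[:-1]
    mu0 = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * omega0 - mu0) ** 2 / (omega0 * (1.0 - omega0))
    between = np.nan_to_num(between, nan=-1.0)
    return float(levels[int(np.argmax(between))])


def otsu_threshold_1d(image: VolumeImage, bright_is_bone: bool = True) -> BinaryVolume:
    """Plain (1D) Otsu threshold applied per axis0 slice."""
    voxels = np.asarray(image.voxels, dtype=float)
    if not bright_is_bone:
        voxels = -voxels
    if np.unique(voxels).size < 2:
        raise ValueError("constant image: Otsu thresholding needs >= 2 distinct values")
    out = np.empty(voxels.shape, dtype=bool)
    for i, sl in enumerate(voxels):
        if np.unique(sl).size < 2:
            out[i] = sl > _otsu_1d_threshold(voxels)
        else:
            out[i] = sl > _otsu_1d_threshold(sl)
    return BinaryVolume(out, image.voxel_size_mm, image.axis_labels)


def _otsu_2d_slice(sl: np.ndarray, n_bins: int) -> np.ndarray:
    """2D Otsu on one slice: joint (intensity, 3x3 local mean) histogram.

    The threshold pair (s, t) maximises the trace of the between-class
    scatter matrix of the two diagonal quadrants (background = both features
    below threshold, foreground = both above).  The joint histogram makes
    the selection noise-robust; the final assignment is by intensity alone,
    so isolated bright/dark pixels do not leak across phase boundaries.
    """
    local_mean = ndimage.uniform_filter(sl, size=3, mode="nearest")
    lo = min(sl.min(), local_mean.min())
    hi = max(sl.max(), local_mean.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    i_bin = np.clip(np.digitize(sl, edges) - 1, 0, n_bins - 1)
    j_bin = np.clip(np.digitize(local_mean, edges) - 1, 0, n_bins - 1)
    hist = np.zeros((n_bins, n_bins))
    np.add.at(hist, (i_bin, j_bin), 1.0)
    p = hist / hist.sum()

    centers = 0.5 * (edges[:-1] + edges[1:])
    # cumulative mass and first moments over the [0..s, 0..t] rectangle
    P = p.cumsum(axis=0).cumsum(axis=1)
    Mi = (p * centers[:, None]).cumsum(axis=0).cumsum(axis=1)
    Mj = (p * centers[None, :]).cumsum(axis=0).cumsum(axis=1)
    mu_i, mu_j = Mi[-1, -1], Mj[-1, -1]

    P0, P1 = P, 1.0 - P
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0_i, mu0_j = Mi / P0, Mj / P0
        mu1_i = (mu_i - Mi) / P1
        mu1_j = (mu_j - Mj) / P1
        trace = P0 * ((mu0_i - mu_i) ** 2 + (mu0_j - mu_j) ** 2) + P1 * (
            (mu1_i - mu_i) ** 2 + (mu1_j - mu_j) ** 2
        )
    trace = np.where((P0 > 0) & (P1 > 0), trace, -1.0)
    s, t = np.unravel_index(int(np.argmax(trace)), trace.shape)
    return i_bin > s


def otsu_threshold(
    image: VolumeImage, bright_is_bone: bool = True, n_bins: int = 64
) -> BinaryVolume:
    """Per-slice 2D Otsu threshold: bone = bright phase of each axis0 slice.

    For every slice the joint histogram of pixel intensity and 3x3-local-mean
    intensity is built and the threshold pair maximising the between-class
    variance chosen; a voxel is bone when both its intensity and its local
    mean exceed their thresholds.  Set ``bright_is_bone=False`` for inverted
    contrast; the output is then identical to thresholding the inverted
    image.
    """
    voxels = np.asarray(image.voxels, dtype=float)
    if not bright_is_bone:
        voxels = -voxels
    if np.unique(voxels).size < 2:
        raise ValueError("constant image: Otsu thresholding needs >= 2 distinct values")
    global_threshold = None
    out = np.empty(voxels.shape, dtype=bool)
    for i, sl in enumerate(voxels):
        if np.unique(sl).size < 2:
            # constant slice: fall back to a volume-wide 1D Otsu split
            if global_threshold is None:
                global_threshold = _otsu_1d_threshold(voxels)
            out[i] = sl > global_threshold
        else:
            out[i] = _otsu_2d_slice(sl, n_bins)
    result = BinaryVolume(out, image.voxel_size_mm, image.axis_labels)
    logger.info(
        "otsu_threshold: shape=%s voxel_size_mm=%g bvtv=%.4f",
        image.shape,
        image.voxel_size_mm,
        result.bvtv(),
    )
    return result


# ---------------------------------------------------------------------------
# despeckle


def _drop_small_components(
    mask: np.ndarray, min_size: int, connectivity: int
) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def despeckle(volume: BinaryVolume, spec: DespeckleSpec | None = None) -> BinaryVolume:
    """Remove bone speckles, then void speckles, below the size threshold.

    Foreground components with fewer than ``min_component_vox`` voxels become
    background; background components below the same threshold then become
    foreground.  The operation is idempotent.
    """
    if spec is None:
        spec = DespeckleSpec()
    v = _drop_small_components(
        volume.voxels, spec.min_component_vox, spec.foreground_connectivity
    )
    bg = ~v
    kept_bg = _drop_small_components(
        bg, spec.min_component_vox, spec.background_connectivity
    )
    v = v | (bg & ~kept_bg)
    result = BinaryVolume(v, volume.voxel_size_mm, volume.axis_labels)
    logger.info(
        "despeckle: min_size=%d bvtv %.4f -> %.4f",
        spec.min_component_vox,
        volume.bvtv(),
        result.bvtv(),
    )
    return result


# ---------------------------------------------------------------------------
# erosion


def erode(volume: BinaryVolume, radius_vox: int) -> BinaryVolume:
    """Binary erosion with a centred cubic kernel of side 2r+1.

    Removes r voxel layers from every free surface of the bone phase;
    r = 0 is the identity.  Voxels beyond the array border count as bone, so
    only bone/void interfaces erode.  Equivalent to keeping each bone voxel
    whose full Chebyshev-r neighbourhood is bone.
    """
    if radius_vox < 0:
        raise ValueError(f"erosion radius must be >= 0, got {radius_vox}")
    if radius_vox == 0:
        return BinaryVolume(
            volume.voxels.copy(), volume.voxel_size_mm, volume.axis_labels
        )
    side = 2 * radius_vox + 1
    eroded = ndimage.minimum_filter(
        volume.voxels.astype(np.uint8), size=side, mode="constant", cval=1
    ).astype(bool)
    result = BinaryVolume(eroded, volume.voxel_size_mm, volume.axis_labels)
    logger.info(
        "erode: radius=%d bvtv %.4f -> %.4f", radius_vox, volume.bvtv(), result.bvtv()
    )
    return result


def disease_pipeline(
    volume: BinaryVolume, erosion_radius_vox: int, spec: DespeckleSpec | None = None
) -> BinaryVolume:
    """Erode an already-thresholded, despeckled volume and clean up fragments.

    Erosion can split thin trabeculae, leaving small isolated fragments; the
    trailing despeckle pass removes them, mirroring the disease-simulation
    order threshold -> despeckle -> erode -> despeckle.
    """
    return despeckle(erode(volume, erosion_radius_vox), spec)
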