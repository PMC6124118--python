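"""Core voxel-volume data model, file I/O, configuration and logging.

Volumes are plain 3D numpy grids indexed ``(axis0, axis1, axis2)`` with an
isotropic physical voxel edge in millimetres.  Slice-stack directories load
with axis0 = slice index (lexicographic filename order).  Anatomical
direction names (superior-inferior, anterior-posterior, medial-lateral, ...)
are user-supplied labels only; no orientation is inferred from files.

All physical geometry is expressed in mm and all spatial frequencies in
mm^-1 throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("trabspec")

__all__ = [
    "VolumeImage",
    "BinaryVolume",
    "FrequencyBand",
    "AnalysisConfig",
    "read_volume",
    "write_volume",
    "write_records",
    "read_records",
    "load_config",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_DEFAULT_AXIS_LABELS = ("axis0", "axis1", "axis2")


def _validate_voxels(voxels: np.ndarray, voxel_size_mm: float) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"volume must be 3D, got {voxels.ndim} dimensions")
    if min(voxels.shape) < 1:
        raise ValueError(f"every axis must have >= 1 voxel, got shape {voxels.shape}")
    if not (voxel_size_mm > 0) or not math.isfinite(voxel_size_mm):
        raise ValueError(f"voxel_size_mm must be positive and finite, got {voxel_size_mm}")


@dataclass(frozen=True)
class VolumeImage:
    """A 3D grayscale voxel grid with isotropic physical voxel size in mm."""

    voxels: np.ndarray
    voxel_size_mm: float
    axis_labels: tuple[str, str, str] = _DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        _validate_voxels(voxels, self.voxel_size_mm)
        if not np.all(np.isfinite(voxels)):
            raise ValueError("volume intensities must all be finite")
        object.__setattr__(self, "voxels", voxels)
        if len(self.axis_labels) != 3:
            raise ValueError("axis_labels must name exactly three axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.voxels.shape)


@dataclass(frozen=True)
class BinaryVolume:
    """A thresholded (two-phase) volume; True marks the bone phase."""

    voxels: np.ndarray
    voxel_size_mm: float
    axis_labels: tuple[str, str, str] = _DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        _validate_voxels(voxels, self.voxel_size_mm)
        if voxels.dtype != bool:
            unique = np.unique(voxels)
            if not np.isin(unique, (0, 1)).all():
                raise ValueError("binary volume must contain exactly two phases (0/1)")
            voxels = voxels.astype(bool)
        object.__setattr__(self, "voxels", voxels)
        if len(self.axis_labels) != 3:
            raise ValueError("axis_labels must name exactly three axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def bvtv(self) -> float:
        """Bone volume fraction (foreground voxels over total)."""
        return float(self.voxels.mean())

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.voxels.shape)


@dataclass(frozen=True)
class FrequencyBand:
    """Inclusive spatial-frequency window [lo, hi] in mm^-1."""

    lo_per_mm: float
    hi_per_mm: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_per_mm < self.hi_per_mm):
            raise ValueError(
                f"band requires 0 < lo < hi, got [{self.lo_per_mm}, {self.hi_per_mm}]"
            )


# Geometry and band defaults: 5 mm cubic VOIs subdivided into 1 x 1 x 5 mm
# prisms; low band [1, 1.8] mm^-1 at the trabecular-spacing scale and high
# band [3.8, 7.4] mm^-1 at the trabecular-thickness scale.
DEFAULT_LOW_BAND = FrequencyBand(1.0, 1.8)
DEFAULT_HIGH_BAND = FrequencyBand(3.8, 7.4)
NARROW_HIGH_BAND = FrequencyBand(3.8, 5.6)


@dataclass(frozen=True)
class AnalysisConfig:
    """Geometry, band and cross-validation settings for the full pipeline."""

    voi_edge_mm: float = 5.0
    prism_cross_mm: float = 1.0
    analysis_axis: int = 0
    nominal_analysis_length_mm: float = 5.0
    low_band: FrequencyBand = DEFAULT_LOW_BAND
    high_band: FrequencyBand = DEFAULT_HIGH_BAND
    despeckle_min_size_vox: int = 125
    erosion_radius_vox: int = 2
    cv_folds: int = 5
    cv_repeats: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.voi_edge_mm <= 0 or self.prism_cross_mm <= 0:
            raise ValueError("voi_edge_mm and prism_cross_mm must be positive")
        ratio = self.voi_edge_mm / self.prism_cross_mm
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"voi_edge_mm={self.voi_edge_mm} must be a positive multiple of "
                f"prism_cross_mm={self.prism_cross_mm}"
            )
        if self.analysis_axis not in (0, 1, 2):
            raise ValueError(f"analysis_axis must be 0, 1 or 2, got {self.analysis_axis}")
        if self.nominal_analysis_length_mm <= 0:
            raise ValueError("nominal_analysis_length_mm must be positive")
        if self.low_band.hi_per_mm >= self.high_band.lo_per_mm:
            raise ValueError(
                "bands overlap: low_band must lie entirely below high_band "
                f"(low=[{self.low_band.lo_per_mm}, {self.low_band.hi_per_mm}], "
                f"high=[{self.high_band.lo_per_mm}, {self.high_band.hi_per_mm}])"
            )
        if self.despeckle_min_size_vox < 1:
            raise ValueError("despeckle_min_size_vox must be >= 1")
        if self.erosion_radius_vox < 0:
            raise ValueError("erosion_radius_vox must be >= 0")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.cv_repeats < 1:
            raise ValueError(f"cv_repeats must be >= 1, got {self.cv_repeats}")

    def prisms_per_voi(self) -> int:
        m = round(self.voi_edge_mm / self.prism_cross_mm)
        return m * m


# ---------------------------------------------------------------------------
# volume readers / writers


def _read_tiff_voxel_size_mm(page) -> float | None:
    """Voxel size from TIFF resolution tags (pixels per unit), if present."""
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimetre
        return 10.0 / pixels_per_unit
    if unit == 2:  # inch
        return 25.4 / pixels_per_unit
    return None


def _read_slice_stack(path: Path, voxel_size_mm: float | None) -> VolumeImage:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES | {".png"}
    )
    if not files:
        raise FileNotFoundError(f"no slice images found in directory {path}")
    slices = []
    meta_size = None
    for f in files:
        if f.suffix.lower() in _TIFF_SUFFIXES:
            with tifffile.TiffFile(f) as tf:
                arr = tf.asarray()
                if meta_size is None:
                    meta_size = _read_tiff_voxel_size_mm(tf.pages[0])
        else:
            from imageio.v3 import imread

            arr = imread(f)
        if arr.ndim != 2:
            raise ValueError(f"slice {f.name} is not 2D (shape {arr.shape})")
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    size = voxel_size_mm if voxel_size_mm is not None else meta_size
    if size is None:
        raise ValueError(
            f"no voxel size metadata in {path} and no voxel_size_mm override given"
        )
    return VolumeImage(np.stack(slices, axis=0), size)


def read_volume(path, voxel_size_mm: float | None = None) -> VolumeImage:
    """Read a volume from a slice-stack directory, a multi-page TIFF or a NIfTI file.

    Slice stacks are assembled in lexicographic filename order with axis0 as
    the slice index.  The voxel size comes from file metadata unless
    ``voxel_size_mm`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume path does not exist: {path}")
    if path.is_dir():
        vol = _read_slice_stack(path, voxel_size_mm)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tf:
            voxels = tf.asarray()
            meta_size = _read_tiff_voxel_size_mm(tf.pages[0])
        if voxels.ndim != 3:
            raise ValueError(f"expected a 3D TIFF volume, got shape {voxels.shape}")
        size = voxel_size_mm if voxel_size_mm is not None else meta_size
        if size is None:
            raise ValueError(
                f"no voxel size metadata in {path} and no voxel_size_mm override given"
            )
        vol = VolumeImage(voxels, size)
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj)
        if voxels.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got shape {voxels.shape}")
        zooms = img.header.get_zooms()[:3]
        size = voxel_size_mm
        if size is None:
            if any(z <= 0 for z in zooms):
                raise ValueError(
                    f"no voxel size metadata in {path} and no voxel_size_mm override given"
                )
            if max(zooms) - min(zooms) > 1e-6 * max(zooms):
                raise ValueError(
                    f"anisotropic voxels {zooms} in {path}; pass voxel_size_mm to override"
                )
            size = float(zooms[0])
        vol = VolumeImage(voxels, size)
    else:
        raise ValueError(f"unsupported volume format: {path}")
    logger.info(
        "read volume %s: shape=%s voxel_size_mm=%g", path, vol.shape, vol.voxel_size_mm
    )
    return vol


def write_volume(volume: VolumeImage | BinaryVolume, path) -> None:
    """Write a volume as a multi-page TIFF, NIfTI file or TIFF slice-stack directory.

    A path with no recognised suffix is treated as a directory and one TIFF
    per axis0 slice is written, preserving read-back order.
    """
    path = Path(path)
    voxels = volume.voxels
    if voxels.dtype == bool:
        voxels = voxels.astype(np.uint8)
    size = volume.voxel_size_mm
    if path.suffix.lower() in _TIFF_SUFFIXES:
        # resolution tags store pixels per cm
        tifffile.imwrite(
            path,
            voxels,
            photometric="minisblack",
            resolution=(10.0 / size, 10.0 / size),
            resolutionunit="CENTIMETER",
        )
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        affine = np.diag([size, size, size, 1.0])
        nib.save(nib.Nifti1Image(voxels, affine), str(path))
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(voxels.shape[0])))
        for i in range(voxels.shape[0]):
            tifffile.imwrite(
                path / f"slice_{i:0{width}d}.tif",
                voxels[i],
                photometric="minisblack",
                resolution=(10.0 / size, 10.0 / size),
                resolutionunit="CENTIMETER",
            )
    logger.info("wrote volume to %s: shape=%s voxel_size_mm=%g", path, volume.shape, size)


# ---------------------------------------------------------------------------
# tabular records


def write_records(records, path) -> None:
    """Write result rows (dicts, dataclasses or a DataFrame) to CSV.

    Floats round-trip at full repr precision; an empty record list still
    produces a header-only file when a DataFrame with columns is passed.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append(
                    {k: getattr(rec, k) for k in rec.__dataclass_fields__}
                )
            else:
                rows.append(dict(rec))
        frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    logger.info("wrote %d records to %s", len(frame), path)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration


_CONFIG_KEYS = {
    "voi_edge_mm",
    "prism_cross_mm",
    "analysis_axis",
    "nominal_analysis_length_mm",
    "low_band",
    "high_band",
    "despeckle_min_size_vox",
    "erosion_radius_vox",
    "cv_folds",
    "cv_repeats",
    "rng_seed",
}


def _parse_band(value, key: str) -> FrequencyBand:
    if isinstance(value, FrequencyBand):
        return value
    if isinstance(value, str):
        parts = value.replace(":", ",").split(",")
        value = [float(p) for p in parts]
    try:
        lo, hi = value
    except (TypeError, ValueError) as err:
        raise ValueError(f"{key}: expected two numbers [lo, hi], got {value!r}") from err
    try:
        return FrequencyBand(float(lo), float(hi))
    except ValueError as err:
        raise ValueError(f"{key}: {err}") from err


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat key-value (YAML) file.

    Absent keys take the documented defaults; unknown keys and invariant
    violations are reported with the offending key names.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    for key in ("low_band", "high_band"):
        if key in kwargs:
            kwargs[key] = _parse_band(kwargs[key], key)
    config = AnalysisConfig(**kwargs)
    logger.info("loaded config from %s: %s", path, config)
    return config
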