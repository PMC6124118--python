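"""One-feature maximum-margin classification of ratio metrics.

The ratio metric is the sole feature of a two-class (healthy vs eroded)
linear support-vector classifier, so the decision rule reduces to a single
threshold on the metric.  Performance is assessed by stratified k-fold
cross-validation repeated many times with fresh partitions; sensitivity is
the fraction of diseased (eroded) volumes classified as diseased and
specificity the fraction of healthy volumes classified as healthy, reported
as mean +/- sd over the repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .mrsim import mean_spectrum, prism_spectra, subdivide_prisms
from .ratio_metric import UndefinedMetricError, ratio_metric
from .volumes_io import AnalysisConfig, FrequencyBand

logger = logging.getLogger("trabspec")

__all__ = [
    "FittedBoundary",
    "ClassifierReport",
    "fit_boundary",
    "predict",
    "apply_classifier",
    "repeated_cv",
    "cross_section_sweep",
]


@dataclass(frozen=True)
class FittedBoundary:
    """Threshold on the metric; ``diseased_above`` records which side is diseased.

    A value exactly at the threshold is assigned to the healthy side (the
    conservative tie rule: boundary shifts toward fewer false negatives are
    an explicit, separate choice).
    """

    threshold: float
    diseased_above: bool


@dataclass(frozen=True)
class ClassifierReport:
    decision_boundary: FittedBoundary
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    n_per_class: tuple[int, int]  # (healthy, diseased)
    folds: int
    repeats: int
    rng_seed: int

    def __post_init__(self) -> None:
        for name in ("sensitivity_mean", "specificity_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("sensitivity_sd", "specificity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _as_arrays(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    return values, labels


def fit_boundary(values, labels, C: float = 1.0) -> FittedBoundary:
    """Maximum-margin threshold on a single feature (linear SVC, hinge loss).

    ``labels`` are boolean, True = diseased.  The feature is standardised
    (z-scored on the training data) before the fit so the hinge objective is
    scale-free, and the threshold is mapped back to metric units.  For
    separable data this gives the midpoint of the inner class extremes;
    otherwise the hinge-loss optimum at regularisation ``C`` on the
    standardised feature.
    """
    values, labels = _as_arrays(values, labels)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to fit a boundary")
    mu = float(values.mean())
    sd = float(values.std())
    if sd == 0.0:
        # all values identical: no information, everything on the healthy side
        return FittedBoundary(threshold=np.inf, diseased_above=True)
    z = (values - mu) / sd
    svc = SVC(kernel="linear", C=C)
    svc.fit(z.reshape(-1, 1), labels.astype(int))
    w = float(svc.coef_[0][0])
    b = float(svc.intercept_[0])
    if w == 0.0:
        # degenerate fit (identical class distributions): everything healthy
        return FittedBoundary(threshold=np.inf, diseased_above=True)
    return FittedBoundary(threshold=mu + sd * (-b / w), diseased_above=w > 0)


def predict(boundary: FittedBoundary, values) -> np.ndarray:
    """Boolean predictions (True = diseased); ties at the threshold are healthy."""
    values = np.asarray(values, dtype=float).ravel()
    if boundary.diseased_above:
        return values > boundary.threshold
    return values < boundary.threshold


def _rates(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    sensitivity = float(pred[labels].mean()) if labels.any() else float("nan")
    specificity = float((~pred[~labels]).mean()) if (~labels).any() else float("nan")
    return sensitivity, specificity


def apply_classifier(boundary: FittedBoundary, values, true_labels=None):
    """Apply a fitted threshold; with labels, also return (sensitivity, specificity)."""
    pred = predict(boundary, values)
    if true_labels is None:
        return pred
    labels = np.asarray(true_labels, dtype=bool).ravel()
    return pred, _rates(pred, labels)


def repeated_cv(
    values,
    labels,
    folds: int = 5,
    repeats: int = 50,
    seed: int = 0,
    pooling: str = "pooled",
) -> ClassifierReport:
    """Repeated stratified k-fold cross-validation of the threshold classifier.

    Per repeat the data are re-partitioned into stratified folds, a boundary
    is fitted on each training split and applied to the held-out fold, and
    the repeat's sensitivity/specificity are computed from the pooled
    held-out predictions (``pooling="per-fold"`` averages per-fold rates
    instead).  The report carries the mean and sample sd over repeats plus a
    boundary fitted on the full data.
    """
    if pooling not in ("pooled", "per-fold"):
        raise ValueError("pooling must be 'pooled' or 'per-fold'")
    values, labels = _as_arrays(values, labels)
    n_diseased = int(labels.sum())
    n_healthy = int(labels.size - n_diseased)
    if min(n_healthy, n_diseased) < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold stratification "
            f"(got healthy={n_healthy}, diseased={n_diseased})"
        )
    rng = np.random.default_rng(seed)
    sens, spec = [], []
    X = values.reshape(-1, 1)
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        if pooling == "pooled":
            pred = np.zeros(labels.size, dtype=bool)
            for train, test in skf.split(X, labels):
                fb = fit_boundary(values[train], labels[train])
                pred[test] = predict(fb, values[test])
            se, sp = _rates(pred, labels)
        else:
            fold_rates = []
            for train, test in skf.split(X, labels):
                fb = fit_boundary(values[train], labels[train])
                fold_rates.append(_rates(predict(fb, values[test]), labels[test]))
            se = float(np.mean([r[0] for r in fold_rates]))
            sp = float(np.mean([r[1] for r in fold_rates]))
        sens.append(se)
        spec.append(sp)
    sens = np.array(sens)
    spec = np.array(spec)
    ddof = 1 if repeats > 1 else 0
    report = ClassifierReport(
        decision_boundary=fit_boundary(values, labels),
        sensitivity_mean=float(sens.mean()),
        sensitivity_sd=float(sens.std(ddof=ddof)),
        specificity_mean=float(spec.mean()),
        specificity_sd=float(spec.std(ddof=ddof)),
        n_per_class=(n_healthy, n_diseased),
        folds=folds,
        repeats=repeats,
        rng_seed=seed,
    )
    logger.info(
        "repeated_cv: folds=%d repeats=%d sens=%.3f+/-%.3f spec=%.3f+/-%.3f",
        folds,
        repeats,
        report.sensitivity_mean,
        report.sensitivity_sd,
        report.specificity_mean,
        report.specificity_sd,
    )
    return report


def cross_section_sweep(
    pairs,
    config: AnalysisConfig,
    m_values=None,
    high_band: FrequencyBand | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Classification accuracy versus prism-count (cross-sectional area).

    ``pairs`` is a sequence of (healthy volume, diseased volume, VOI)
    triples; the VOI indexes both volumes of a pair.  For each m the ratio
    metric is recomputed from the mean spectrum of the first m prisms in
    row-major grid order (m prisms of 1 mm^2 each = m mm^2 of acquired
    cross-section), and the repeated-CV report is computed on the resulting
    healthy/diseased metric values.  ``high_band`` overrides the high band
    (e.g. the narrow [3.8, 5.6] mm^-1 variant).

    Returns one row per m with accuracy/sensitivity/specificity means and
    sds; m equal to the full prism count reproduces the standard pipeline.
    """
    if high_band is None:
        high_band = config.high_band
    length = config.nominal_analysis_length_mm
    per_condition_spectra = {"healthy": [], "diseased": []}
    n_prisms = None
    for healthy_vol, diseased_vol, voi in pairs:
        prisms = subdivide_prisms(voi, config.prism_cross_mm, healthy_vol.voxel_size_mm)
        if n_prisms is None:
            n_prisms = len(prisms)
        elif len(prisms) != n_prisms:
            raise ValueError("all VOIs must yield the same prism count")
        per_condition_spectra["healthy"].append(prism_spectra(healthy_vol, prisms))
        per_condition_spectra["diseased"].append(prism_spectra(diseased_vol, prisms))
    if m_values is None:
        m_values = range(1, n_prisms + 1)
    rows = []
    for m in m_values:
        if not 1 <= m <= n_prisms:
            raise ValueError(f"m={m} outside 1..{n_prisms}")
        values, labels = [], []
        n_undefined = 0
        for condition, is_diseased in (("healthy", False), ("diseased", True)):
            for spectra in per_condition_spectra[condition]:
                spec = mean_spectrum(spectra[:m])
                try:
                    values.append(
                        ratio_metric(spec, config.low_band, high_band, length)
                    )
                except UndefinedMetricError:
                    # e.g. an all-void prism subset on heavily eroded bone:
                    # recorded as missing and excluded from classification
                    n_undefined += 1
                    continue
                labels.append(is_diseased)
        if n_undefined:
            logger.warning(
                "cross_section_sweep m=%d: %d undefined metrics excluded",
                m,
                n_undefined,
            )
        report = repeated_cv(
            values,
            labels,
            folds=config.cv_folds,
            repeats=config.cv_repeats,
            seed=seed,
        )
        accuracy = 0.5 * (report.sensitivity_mean + report.specificity_mean)
        rows.append(
            {
                "m_prisms": int(m),
                "cross_section_area_mm2": m * config.prism_cross_mm**2,
                "accuracy_mean": accuracy,
                "sensitivity_mean": report.sensitivity_mean,
                "sensitivity_sd": report.sensitivity_sd,
                "specificity_mean": report.specificity_mean,
                "specificity_sd": report.specificity_sd,
            }
        )
    return pd.DataFrame(rows)
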