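"""Pixel-wise classification metrics, rank correlation and mass bookkeeping.

The segmentation quality indicators are the usual confusion-matrix derived
quantities: precision (correctly flagged decay among flagged), sensitivity
(correctly flagged decay among actual decay), specificity, accuracy, and the
F1 score — the harmonic mean of precision and sensitivity, used both for
model selection and for threshold calibration. Benchmarks against field
measurements use Spearman rank correlation; the disc-based dry-mass
estimator extrapolates a log's dry mass from its end disc:

    dry_mass_log = fresh_mass_log / fresh_mass_disc * dry_mass_disc
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ctvolume import ParameterError


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    """Fractions in [0, 1]; ``None`` marks an undefined metric (zero
    denominator) — never silently 0 or 1, the caller decides."""

    precision: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in self.__dict__.items()
        }


def confusion_counts(
    predicted: np.ndarray,
    truth: np.ndarray,
    evaluation_region: np.ndarray | None = None,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN over the evaluation region (everywhere by default)."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    if evaluation_region is not None:
        region = np.asarray(evaluation_region).astype(bool)
        if region.shape != predicted.shape:
            raise ValueError("evaluation_region shape mismatch")
        predicted, truth = predicted[region], truth[region]
    return ConfusionCounts(
        tp=int(np.sum(predicted & truth)),
        fp=int(np.sum(predicted & ~truth)),
        fn=int(np.sum(~predicted & truth)),
        tn=int(np.sum(~predicted & ~truth)),
    )


def classification_metrics(c: ConfusionCounts) -> ClassMetrics:
    """Precision, sensitivity, specificity, accuracy and F1 from counts."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    precision = ratio(c.tp, c.tp + c.fp)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    accuracy = ratio(c.tp + c.tn, c.total)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return ClassMetrics(precision, sensitivity, specificity, accuracy, f1)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (handles ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise UndefinedMetricError("constant vector: rank correlation undefined")
    return float(rx @ ry) / denom


def spearman(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    For n <= ``exact_max_n`` the p-value is exact (enumeration over all
    permutations of one vector); for larger n the usual t-approximation is
    used. Ties get average ranks in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and equally long")
    n = x.size
    if n < 3:
        raise ParameterError("need n >= 3 for a rank test")
    rho = _rank_rho(x, y)
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        observed = abs(rho)
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _rank_rho(x, np.array(perm))
            hits += abs(r) >= observed - 1e-12
            total += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho=rho, p_value=float(p), n=n)


@dataclass(frozen=True)
class MassRecord:
    """Fresh/dry masses in grams, recorded to 0.1 g."""

    fresh_mass_log: float
    fresh_mass_disc: float
    dry_mass_disc: float
    measured_dry_mass_log: float | None = None

    def __post_init__(self) -> None:
        if min(self.fresh_mass_log, self.fresh_mass_disc, self.dry_mass_disc) <= 0:
            raise ParameterError("masses must be positive")
        if self.dry_mass_disc > self.fresh_mass_disc:
            raise ParameterError("dry mass cannot exceed fresh mass for the disc")


def estimate_log_dry_mass(r: MassRecord) -> float:
    """Disc-based dry-mass extrapolation:
    ``fresh_mass_log / fresh_mass_disc * dry_mass_disc``."""
    return r.fresh_mass_log / r.fresh_mass_disc * r.dry_mass_disc


def relative_mass_loss(initial_dry: float, final_dry: float) -> float:
    """Dry-mass loss in percent; negative when the estimate gained mass.

    Negative values are real outcomes of disc-based estimation: within-log
    heterogeneity can make the extrapolated initial mass undershoot.
    """
    if initial_dry <= 0:
        raise ParameterError("initial dry mass must be positive")
    return 100.0 * (initial_dry - final_dry) / initial_dry
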