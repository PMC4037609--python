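"""Entropy-weighted correlation benchmarking and the AUROC baseline.

The headline statistic is the weighted Pearson correlation coefficient
(wPCC) between observed effect quotients X (empirical q values) and
predicted quotients Y:

    r = sum_i w_i (X_i - Xbar)(Y_i - Ybar)
        / sqrt(sum_i w_i (X_i - Xbar)^2) / sqrt(sum_i w_i (Y_i - Ybar)^2)

with weighted means Zbar = sum w_i Z_i / sum w_i.  Weights are
nonnegative appraisals of each observation's worth; entropy weighting
sets w_i = H(q_i) * quality_i so that saturated observations (q of 0 or
1) drop out entirely and half-maximal ones count most.

For contrast with conventional practice, ``dichotomize_and_auroc``
implements the usual cutoff-plus-AUROC benchmark: observations are
dichotomized at a cutoff and predictions scored by the area under the
ROC curve (rank-based, midrank tie handling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateDataError, ParameterError, UndefinedCorrelationError
from .informativeness import assign_weight

__all__ = [
    "BenchmarkPair",
    "BenchmarkResult",
    "weighted_mean",
    "weighted_pcc",
    "entropy_weighted_benchmark",
    "dichotomize_and_auroc",
]


@dataclass(frozen=True)
class BenchmarkPair:
    """One observed/predicted pair with its nonnegative weight."""

    x_observed: float
    y_predicted: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.weight >= 0):
            raise ParameterError(f"weight must be >= 0, got {self.weight!r}")


@dataclass(frozen=True)
class BenchmarkResult:
    """Summary of one benchmarking run."""

    wpcc: Optional[float]
    n_total: int
    n_effective: int
    weight_sum: float
    weighted_mean_x: Optional[float] = None
    weighted_mean_y: Optional[float] = None
    auroc: Optional[float] = None
    cutoff: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None or k in ("wpcc", "n_total", "n_effective", "weight_sum")
        }


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean sum(w_i Z_i) / sum(w_i).

    Uniform weights reduce it to the plain mean; a zero weight removes its
    point.  Empty input or all-zero weights raise
    :class:`DegenerateDataError`.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ParameterError(
            f"values and weights differ in length: {v.shape} vs {w.shape}"
        )
    if v.size == 0:
        raise DegenerateDataError("weighted_mean of empty input")
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DegenerateDataError("all weights are zero")
    return float((w * v).sum() / total)


def weighted_pcc(pairs: Sequence[BenchmarkPair]) -> BenchmarkResult:
    """Weighted Pearson correlation over observed/predicted pairs.

    Invariant under positive affine transforms of X and of Y and under
    rescaling all weights by a positive constant; equal weights reproduce
    the unweighted PCC.  Requires at least two pairs with positive weight
    and positive weighted variance in both coordinates.
    """
    if len(pairs) == 0:
        raise DegenerateDataError("no pairs supplied")
    x = np.array([p.x_observed for p in pairs], dtype=float)
    y = np.array([p.y_predicted for p in pairs], dtype=float)
    w = np.array([p.weight for p in pairs], dtype=float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ParameterError("non-finite observed or predicted values; inputs must be complete")

    n_eff = int((w > 0).sum())
    if n_eff < 2:
        raise DegenerateDataError(
            f"need >= 2 pairs with positive weight, have {n_eff}"
        )
    w_sum = float(w.sum())
    xbar = float((w * x).sum() / w_sum)
    ybar = float((w * y).sum() / w_sum)
    dx = x - xbar
    dy = y - ybar
    sxx = float((w * dx * dx).sum())
    syy = float((w * dy * dy).sum())
    if sxx <= 0 or syy <= 0:
        raise UndefinedCorrelationError(
            "zero weighted variance in "
            + ("X" if sxx <= 0 else "Y")
            + "; correlation undefined"
        )
    r = float((w * dx * dy).sum() / (np.sqrt(sxx) * np.sqrt(syy)))
    r = min(1.0, max(-1.0, r))  # guard rounding just past +/-1
    return BenchmarkResult(
        wpcc=r,
        n_total=len(pairs),
        n_effective=n_eff,
        weight_sum=w_sum,
        weighted_mean_x=xbar,
        weighted_mean_y=ybar,
    )


def entropy_weighted_benchmark(
    observed_q: Sequence[float],
    predicted_q: Sequence[float],
    quality: Optional[Sequence[float]] = None,
) -> BenchmarkResult:
    """Benchmark predictions against observed quotients with entropy weights.

    Each pair gets weight ``H(q_i) * quality_i`` so that saturated
    observations contribute nothing.  If every observed q is 0 or 1 the
    dataset carries no benchmarking information and a
    :class:`DegenerateDataError` says so.
    """
    obs = np.asarray(observed_q, dtype=float)
    pred = np.asarray(predicted_q, dtype=float)
    if obs.shape != pred.shape:
        raise ParameterError("observed and predicted lengths differ")
    qual = np.ones_like(obs) if quality is None else np.asarray(quality, dtype=float)
    if qual.shape != obs.shape:
        raise ParameterError("quality length differs from data length")
    weights = np.asarray(assign_weight(obs, qual), dtype=float)
    if not np.any(weights > 0):
        raise DegenerateDataError(
            "all observed quotients are 0 or 1: the dataset is minimally "
            "informative and every entropy weight is zero"
        )
    pairs = [
        BenchmarkPair(float(xi), float(yi), float(wi))
        for xi, yi, wi in zip(obs, pred, weights)
    ]
    return weighted_pcc(pairs)


def dichotomize_and_auroc(
    observed_q: Sequence[float],
    predicted_q: Sequence[float],
    cutoff: float = 0.5,
) -> BenchmarkResult:
    """Conventional baseline: dichotomize observations, score by AUROC.

    Observations with ``q >= cutoff`` are labelled positive.  The AUROC is
    computed from midranks (Mann-Whitney form), so tied predictions count
    half and constant predictions give exactly 0.5.  Requires both classes
    nonempty after dichotomization.
    """
    if not (0.0 < cutoff < 1.0):
        raise ParameterError(f"cutoff must be strictly inside (0,1), got {cutoff!r}")
    obs = np.asarray(observed_q, dtype=float)
    pred = np.asarray(predicted_q, dtype=float)
    if obs.shape != pred.shape:
        raise ParameterError("observed and predicted lengths differ")
    labels = obs >= cutoff
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError(
            f"dichotomization at {cutoff} leaves one class empty "
            f"({n_pos} positive, {n_neg} negative)"
        )
    ranks = rankdata(pred)  # midranks for ties
    auroc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return BenchmarkResult(
        wpcc=None,
        n_total=obs.size,
        n_effective=obs.size,
        weight_sum=float(obs.size),
        auroc=float(auroc),
        cutoff=cutoff,
    )
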