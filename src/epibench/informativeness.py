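"""Effect normalization and Shannon-entropy informativeness weighting.

An antibody-mediated biological effect of observed magnitude B, relative
to its maximum magnitude B_0, defines the effect quotient ``q = B/B_0`` in
[0, 1], interpreted as the probability of one of two alternative states of
the assayed system (inhibited vs active, survived vs died).  The binary
Shannon entropy

    H(q) = -(q log2 q + (1-q) log2 (1-q))      [bits]

measures how informative that observation is for benchmarking a
prediction: maximal (1 bit) at the half-maximal effect q = 1/2, zero at
q in {0, 1} where the dose-response curve is saturated and the
observation constrains nothing.  H is an upper bound on the benchmarking
weight w; a measurement-quality factor in [0, 1] scales it down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import xlogy

from .errors import EffectRangeError, ParameterError

__all__ = [
    "EffectObservation",
    "normalize_effect",
    "shannon_entropy",
    "assign_weight",
    "percent_to_quotient",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class EffectObservation:
    """A normalized effect quotient with its informativeness annotation.

    ``weight = entropy * quality`` and so never exceeds the entropy;
    ``assay_category`` is one of {"inhibition", "survival", "other"}.
    """

    q: float
    entropy: float
    b_observed: float = field(default=1.0)
    b_max: float = 1.0
    quality: float = 1.0
    weight: float = None  # type: ignore[assignment]
    assay_category: str = "other"
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise EffectRangeError(f"q must be in [0,1], got {self.q!r}")
        if not (0.0 <= self.quality <= 1.0):
            raise ParameterError(f"quality must be in [0,1], got {self.quality!r}")
        if self.weight is None:
            object.__setattr__(self, "weight", self.entropy * self.quality)


def normalize_effect(b_observed: float, b_max: float = 1.0, *, clamp: bool = False) -> float:
    """Normalize an observed effect magnitude to the quotient q = B/B_0.

    For inhibition assays B is the fractional activity loss (B_0 = 1, i.e.
    complete loss); for survival assays B is the fraction of surviving
    hosts (B_0 = 1, complete protection).  Counts work directly:
    ``normalize_effect(7, 10)`` is 0.7 survival.

    Out-of-range results (e.g. >100% inhibition from assay noise) raise
    :class:`EffectRangeError` by default; ``clamp=True`` instead maps them
    to the nearest endpoint with a warning.
    """
    if not (b_max > 0):
        raise ParameterError(f"b_max must be > 0, got {b_max!r}")
    if b_observed < 0:
        raise ParameterError(f"b_observed must be >= 0, got {b_observed!r}")
    q = b_observed / b_max
    if q > 1.0:
        if clamp:
            import warnings

            warnings.warn(f"effect quotient {q:g} > 1 clamped to 1", stacklevel=2)
            return 1.0
        raise EffectRangeError(
            f"observed effect {b_observed!r} exceeds maximum {b_max!r}"
        )
    return q


def shannon_entropy(q):
    """Binary Shannon entropy of an effect quotient, in bits.

    ``H = -(q log2 q + (1-q) log2 (1-q))`` with the 0*log(0) := 0
    continuity convention.  Symmetric about 1/2, where it attains its
    maximum of exactly one bit; zero iff q is 0 or 1.

    Accepts scalars or arrays; raises on values outside [0, 1].
    """
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise EffectRangeError(f"q must be in [0,1], got {q!r}")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / _LN2
    # exact endpoints: xlogy already gives 0 at q in {0,1}; clean -0.0
    h = np.abs(h)
    return h if h.ndim else float(h)


def assign_weight(q, quality=1.0):
    """Benchmarking weight ``w = H(q) * quality``.

    The entropy is an upper bound on w, attained at maximum measurement
    quality (quality = 1, the default).  There is no rule for deriving
    quality from assay metadata; it is a caller-supplied scalar in [0, 1].
    The weight is zero whenever q is 0 or 1, regardless of quality.
    """
    quality_arr = np.asarray(quality, dtype=float)
    if np.any((quality_arr < 0) | (quality_arr > 1)):
        raise ParameterError(f"quality must be in [0,1], got {quality!r}")
    w = shannon_entropy(q) * quality_arr
    return w if np.ndim(w) else float(w)


def percent_to_quotient(text_value, *, clamp: bool = False) -> float:
    """Convert a percentage (string or number) to a quotient in [0, 1].

    Strips a trailing "%" and surrounding whitespace, divides by 100.
    Values outside [0, 100] raise :class:`EffectRangeError` under the
    default strict policy; ``clamp=True`` maps them to the nearest
    endpoint with a warning.
    """
    if isinstance(text_value, str):
        cleaned = text_value.strip().rstrip("%").strip()
        try:
            value = float(cleaned)
        except ValueError as exc:
            raise ParameterError(
                f"cannot parse percentage from {text_value!r}"
            ) from exc
    else:
        value = float(text_value)
        if np.isnan(value):
            raise ParameterError("cannot parse percentage from NaN")
    if not (0.0 <= value <= 100.0):
        if clamp:
            import warnings

            clamped = min(max(value, 0.0), 100.0)
            warnings.warn(
                f"percentage {value:g} outside [0,100] clamped to {clamped:g}",
                stacklevel=2,
            )
            value = clamped
        else:
            raise EffectRangeError(
                f"percentage {value!r} outside [0, 100]"
            )
    return value / 100.0
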