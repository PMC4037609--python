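"""Equilibrium antibody-binding and dose-response forward models.

These are the mechanistic pieces that turn an antibody concentration and
affinity into a predicted biological-effect quotient:

* ``bound_fraction`` — fraction of antigen sites occupied by antibody at
  equilibrium, under antibody excess: ``f = 1 / (1 + (K_D/[Ab])^n)``.
  With ``n = 1`` this is the simple single-site binding isotherm; ``n > 1``
  is the Hill generalization for cooperative binding.
* ``outcome_probability`` — the phenomenological dose-response law
  ``p = 1 / (1 + (C_m/C)^b)`` relating the dose of a causative agent
  (toxin, pathogen) to the probability of a biological outcome; ``C_m`` is
  a median effective dose (LD50, ID50, LC50, ...).
* ``free_agent_concentration`` — the free (unbound) agent concentration
  ``C = C_0 / (1 + [Ab]/K_D)`` remaining after equilibrium sequestration
  by antibody (simple, non-cooperative form).
* ``predict_effect_quotient`` — the composition of the above: sequester,
  dilute, challenge.  Its output is directly comparable to an empirical
  effect quotient q.
* ``predicted_dose_ratio`` and ``provisional_ec50_geomean`` — estimators
  for antibody-mediated shifts in apparent median effective dose and for
  a provisional EC50 bracketed by two antibody concentrations.

All concentrations are molar (or any single consistent concentration
unit); arbitrary assay-specific titer units are not supported.  Functions
accept scalars or numpy arrays and evaluate the logistic forms through
``scipy.special.expit`` on the log-concentration scale, which is exact in
the limits and immune to overflow for extreme concentration ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ParameterError

__all__ = [
    "BindingModel",
    "ChallengeModel",
    "AssayCondition",
    "bound_fraction",
    "outcome_probability",
    "free_agent_concentration",
    "predict_effect_quotient",
    "predicted_dose_ratio",
    "provisional_ec50_geomean",
]


@dataclass(frozen=True)
class BindingModel:
    """Equilibrium antibody-antigen binding parameters.

    Parameters
    ----------
    kd
        Dissociation constant, molar, > 0.  The antibody concentration at
        which half of the antigen's antibody-binding sites are occupied.
    hill_n
        Interaction (Hill) coefficient, dimensionless, > 0.  A lower bound
        on the number of antibody binding sites; 1 recovers the simple
        non-cooperative isotherm.  Real-valued, as fitted empirically.
    """

    kd: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise ParameterError(f"kd must be > 0, got {self.kd!r}")
        if not (self.hill_n > 0):
            raise ParameterError(f"hill_n must be > 0, got {self.hill_n!r}")


@dataclass(frozen=True)
class ChallengeModel:
    """Dose-response parameters for challenge with a causative agent.

    Parameters
    ----------
    c_m
        Median effective dose (or concentration) of the causative agent,
        in the same units as the dose argument, > 0.  The outcome
        probability at dose ``c_m`` is exactly one half.
    b
        Empirical steepness coefficient, dimensionless, > 0.
    """

    c_m: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c_m > 0):
            raise ParameterError(f"c_m must be > 0, got {self.c_m!r}")
        if not (self.b > 0):
            raise ParameterError(f"b must be > 0, got {self.b!r}")


@dataclass(frozen=True)
class AssayCondition:
    """Concentrations and dilution defining one assay setup.

    ``antibody_conc`` is the (excess) antibody concentration [Ab];
    ``total_agent_conc`` is the total concentration C_0 of causative agent,
    free plus antibody-bound, before any pre-assay dilution;
    ``dilution_factor`` >= 1 is applied to the free-agent concentration
    before evaluating the challenge dose-response.
    """

    antibody_conc: float
    total_agent_conc: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.antibody_conc >= 0):
            raise ParameterError(
                f"antibody_conc must be >= 0, got {self.antibody_conc!r}"
            )
        if not (self.total_agent_conc >= 0):
            raise ParameterError(
                f"total_agent_conc must be >= 0, got {self.total_agent_conc!r}"
            )
        if not (self.dilution_factor >= 1):
            raise ParameterError(
                f"dilution_factor must be >= 1, got {self.dilution_factor!r}"
            )


def _log_logistic(conc, half_point: float, exponent: float):
    """expit(exponent * ln(conc/half_point)), with the conc=0 limit -> 0."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ParameterError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        out = expit(exponent * (np.log(conc) - np.log(half_point)))
    out = np.where(conc == 0, 0.0, out)
    return out if out.ndim else float(out)


def bound_fraction(model: BindingModel, antibody_conc):
    """Fraction of antigen sites antibody-bound at equilibrium.

    ``f = 1 / (1 + (kd/[Ab])^n)``; 0 at [Ab] = 0 (continuous limit), 1/2 at
    [Ab] = kd, strictly increasing in [Ab], always in [0, 1).

    Accepts a scalar or array of antibody concentrations (molar).
    """
    return _log_logistic(antibody_conc, model.kd, model.hill_n)


def outcome_probability(model: ChallengeModel, dose):
    """Probability of the adverse biological outcome at the given dose.

    ``p = 1 / (1 + (c_m/C)^b)``; 0 at zero dose, exactly 1/2 at the median
    effective dose ``c_m``, strictly increasing in dose.
    """
    return _log_logistic(dose, model.c_m, model.b)


def free_agent_concentration(model: BindingModel, condition: AssayCondition):
    """Free (unbound) causative-agent concentration after antibody binding.

    ``C = C_0 / (1 + [Ab]/kd)`` — the simple non-cooperative (n = 1) form;
    the model's ``hill_n`` is deliberately not applied here.  Equals C_0 at
    zero antibody and satisfies ``C/C_0 = 1 - bound_fraction`` for n = 1.
    """
    return condition.total_agent_conc / (1.0 + condition.antibody_conc / model.kd)


def predict_effect_quotient(
    binding: BindingModel,
    challenge: ChallengeModel,
    condition: AssayCondition,
    *,
    protective: bool = False,
) -> float:
    """Predicted effect quotient q from antibody concentration and affinity.

    Sequesters agent (``free_agent_concentration``), corrects for pre-assay
    dilution by dividing the free concentration by ``dilution_factor``, then
    evaluates the challenge dose-response.

    By default returns the probability of the adverse outcome (the raw
    dose-response value), which is the natural q for inhibition-style
    readouts of the causative agent's effect.  With ``protective=True``
    returns the complement ``1 - p``, the survival/protection probability,
    so survival-type assays map onto q directly.
    """
    free_c = free_agent_concentration(binding, condition)
    dose = free_c / condition.dilution_factor
    p = outcome_probability(challenge, dose)
    return 1.0 - p if protective else p


def predicted_dose_ratio(model: BindingModel, antibody_conc):
    """Ratio of baseline to apparently increased median effective dose.

    An antibody that sequesters a fraction f of the agent makes the agent's
    median effective dose appear larger by 1/(1-f); the baseline-to-shifted
    dose ratio is therefore the complement of the bound fraction,
    ``1 - f = 1 / (1 + [Ab]/kd)`` for n = 1.  Equals 1 at zero antibody.
    """
    f = bound_fraction(model, antibody_conc)
    return 1.0 - f


def provisional_ec50_geomean(low_conc: float, high_conc: float) -> float:
    """Provisional median effective antibody concentration from two endpoints.

    When a titration shows a baseline (q = 0) response at ``low_conc`` and a
    maximal (q = 1) response at ``high_conc``, the median effective
    concentration lies between them and is provisionally estimated as their
    geometric mean — the natural midpoint of a serial-dilution series.

    Arguments may be given in either order (swapped with a warning).
    """
    if not (low_conc > 0) or not (high_conc > 0):
        raise ParameterError(
            f"concentrations must be > 0, got {low_conc!r}, {high_conc!r}"
        )
    if low_conc > high_conc:
        import warnings

        warnings.warn(
            "low_conc > high_conc; swapping endpoints", stacklevel=2
        )
        low_conc, high_conc = high_conc, low_conc
    return float(np.sqrt(low_conc) * np.sqrt(high_conc))
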