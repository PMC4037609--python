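"""Synthetic IEDB-style fixtures and simulated dose-response assays.

Two families of generators, both fully deterministic under an integer
seed:

* ``generate_fixture`` writes an IEDB-schema B-cell assay CSV whose
  composition (numbers of quantitative point estimates, inequality-flagged
  bounds, blank measurements, non-biological-activity assays, per-type
  and positive/negative counts) is known exactly, so the curation
  pipeline can be checked against ground truth record for record.

* ``simulate_inhibition_assay`` / ``simulate_survival_assay`` produce
  dose-response observations from the equilibrium binding and challenge
  models: inhibition readouts are the bound fraction plus Gaussian
  measurement noise (clamped to [0, 1]); survival readouts are binomial
  counts of surviving hosts at each antibody concentration.

``recover_parameters`` closes the loop: it refits the binding model to
simulated observations by least squares on log-concentration, weighting
each point by its binary Shannon entropy so that saturated observations
(q near 0 or 1) carry no influence — the same informativeness weighting
used for benchmarking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .binding import BindingModel, ChallengeModel, AssayCondition, bound_fraction, predict_effect_quotient
from .curation import BIOLOGICAL_ACTIVITY_ASSAY_TYPES, DEFAULT_COLUMN_MAP
from .errors import FitError, FixtureSpecError, ParameterError
from .informativeness import shannon_entropy

__all__ = [
    "FixtureSpec",
    "SimulatedAssay",
    "generate_fixture",
    "simulate_inhibition_assay",
    "simulate_survival_assay",
    "recover_parameters",
]

_QUANT_TYPES = (
    "Neutralization/inhibition of antigen activity",
    "Survival after challenge",
)
_NON_BIOLOGICAL_TYPES = (
    "ELISA binding",
    "Immunoblot (western blot)",
    "Surface plasmon resonance",
)
_POSITIVE_VARIANTS = ("Positive", "Positive-High", "Positive-Intermediate", "Positive-Low")


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth composition of a synthetic IEDB CSV fixture.

    ``n_quant_point`` records carry numeric percentage point estimates
    (values from ``q_values`` if given, else uniform draws); ``n_inequality``
    carry a numeric value flagged as a bound; ``n_empty`` have a blank
    measurement; ``n_nonbiological`` use assay types outside the
    biological-activity tree.  ``per_assay_type_counts`` optionally pins the
    assay-type distribution of the quantitative records.
    """

    n_quant_point: int = 10
    n_inequality: int = 3
    n_empty: int = 5
    n_nonbiological: int = 4
    per_assay_type_counts: Optional[Dict[str, int]] = None
    q_values: Optional[Tuple[float, ...]] = None
    positive_fraction: float = 0.65
    seed: int = 0
    grouped_header: bool = False

    def __post_init__(self) -> None:
        for name in ("n_quant_point", "n_inequality", "n_empty", "n_nonbiological"):
            if getattr(self, name) < 0:
                raise FixtureSpecError(f"{name} must be >= 0")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise FixtureSpecError("positive_fraction must be in [0,1]")
        if self.q_values is not None and len(self.q_values) != self.n_quant_point:
            raise FixtureSpecError(
                f"q_values has {len(self.q_values)} entries for "
                f"{self.n_quant_point} quantitative records"
            )
        if self.per_assay_type_counts is not None:
            if any(v < 0 for v in self.per_assay_type_counts.values()):
                raise FixtureSpecError("per_assay_type_counts must be >= 0")
            if sum(self.per_assay_type_counts.values()) != self.n_quant_point:
                raise FixtureSpecError(
                    "per_assay_type_counts must sum to n_quant_point"
                )

    @property
    def n_total(self) -> int:
        return self.n_quant_point + self.n_inequality + self.n_empty + self.n_nonbiological


def _units_for(method: str) -> str:
    return "survival [%]" if "survival" in method.lower() or "protection" in method.lower() else "inhibition [%]"


def generate_fixture(spec: FixtureSpec, path=None) -> Tuple[pd.DataFrame, dict]:
    """Emit an IEDB-schema CSV fixture with known ground truth.

    Returns ``(frame, ground_truth)``; if ``path`` is given the CSV is
    written there (plus ``<path>.truth.json`` with the ground truth).
    Curating the file recovers exactly the spec's tallies.  Byte-for-byte
    reproducible for a fixed spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    rows: List[dict] = []
    truth_counts: Dict[str, Dict[str, int]] = {}
    next_id = 1000

    def _new_row(method: str, qualitative: str) -> dict:
        nonlocal next_id
        next_id += 1
        return {
            "bcell_id": str(next_id),
            "epitope_id": str(50000 + next_id),
            "pubmed_id": str(9000000 + int(rng.integers(0, 999999))),
            "epitope_type": "Linear peptide",
            "immunogen_epitope_relation": "Epitope",
            "method_technique": method,
            "qualitative_measure": qualitative,
            "quantitative_measurement": "",
            "measurement_inequality": "",
            "assay_type_units": "",
        }

    def _qualitative(q: Optional[float]) -> str:
        if q is not None:
            # qualitative curation consistent with the measurement
            if q > 0:
                return str(rng.choice(_POSITIVE_VARIANTS))
            return "Negative"
        positive = rng.random() < spec.positive_fraction
        if positive:
            return str(rng.choice(_POSITIVE_VARIANTS))
        return "Negative"

    # quantitative point estimates
    if spec.per_assay_type_counts is not None:
        methods = [m for m, k in spec.per_assay_type_counts.items() for _ in range(k)]
    else:
        methods = [str(rng.choice(_QUANT_TYPES)) for _ in range(spec.n_quant_point)]
    if spec.q_values is not None:
        qs = list(spec.q_values)
    else:
        qs = [float(np.round(rng.uniform(0, 1), 4)) for _ in range(spec.n_quant_point)]
    expected_q: List[Tuple[str, float]] = []
    for method, q in zip(methods, qs):
        row = _new_row(method, _qualitative(q))
        row["quantitative_measurement"] = f"{q * 100:.6g}"
        row["assay_type_units"] = _units_for(method)
        rows.append(row)
        expected_q.append((row["bcell_id"], q))

    # inequality-flagged bounds
    for _ in range(spec.n_inequality):
        method = str(rng.choice(_QUANT_TYPES))
        row = _new_row(method, _qualitative(None))
        row["quantitative_measurement"] = f"{rng.uniform(0, 100):.4g}"
        row["measurement_inequality"] = str(rng.choice(["<", ">"]))
        row["assay_type_units"] = _units_for(method)
        rows.append(row)

    # blank measurements on biological-activity assays
    for _ in range(spec.n_empty):
        method = str(rng.choice(BIOLOGICAL_ACTIVITY_ASSAY_TYPES))
        row = _new_row(method, _qualitative(None))
        row["assay_type_units"] = _units_for(method)
        rows.append(row)

    # records outside the biological-activity assay tree
    for _ in range(spec.n_nonbiological):
        rows.append(_new_row(str(rng.choice(_NON_BIOLOGICAL_TYPES)), _qualitative(None)))

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    for row in rows:
        method = row["method_technique"]
        if method in BIOLOGICAL_ACTIVITY_ASSAY_TYPES:
            t = truth_counts.setdefault(method, {"total": 0, "positive": 0, "negative": 0})
            t["total"] += 1
            if row["qualitative_measure"].startswith("Positive"):
                t["positive"] += 1
            else:
                t["negative"] += 1

    frame = pd.DataFrame(
        rows, columns=list(DEFAULT_COLUMN_MAP.keys())
    ).rename(columns=DEFAULT_COLUMN_MAP)
    truth = {
        "n_input": spec.n_total,
        "n_quantitative": spec.n_quant_point,
        "n_excluded_inequality": spec.n_inequality,
        "n_excluded_empty": spec.n_empty,
        "n_excluded_assay_type": spec.n_nonbiological,
        "q_by_bcell_id": {bid: q for bid, q in expected_q},
        "counts": truth_counts,
    }
    if path is not None:
        if spec.grouped_header:
            group_row = ",".join(["Assay"] * len(frame.columns))
            header_row = ",".join(frame.columns)
            body = frame.to_csv(index=False, header=False)
            text = group_row + "\n" + header_row + "\n" + body
            with open(path, "w", newline="") as fh:
                fh.write(text)
        else:
            frame.to_csv(path, index=False)
        with open(str(path) + ".truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return frame, truth


@dataclass(frozen=True)
class SimulatedAssay:
    """Configuration for one simulated dose-response experiment."""

    binding: BindingModel
    ab_grid: Tuple[float, ...]
    challenge: Optional[ChallengeModel] = None
    total_agent_conc: Optional[float] = None
    n_subjects: Optional[int] = None
    noise_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ab_grid) == 0 or any(a < 0 for a in self.ab_grid):
            raise ParameterError("ab_grid must be nonempty with nonnegative entries")


def simulate_inhibition_assay(sim: SimulatedAssay) -> List[Tuple[float, float]]:
    """Inhibition readouts: bound fraction plus Gaussian noise, clamped.

    ``q = clip(f([Ab]) + N(0, noise_sd), 0, 1)`` per grid point; with
    ``noise_sd = 0`` the model curve is reproduced exactly.
    """
    if sim.noise_sd is None or sim.noise_sd < 0:
        raise ParameterError("inhibition simulation requires noise_sd >= 0")
    rng = np.random.default_rng(sim.seed)
    ab = np.asarray(sim.ab_grid, dtype=float)
    truth = np.asarray(bound_fraction(sim.binding, ab), dtype=float)
    noise = rng.normal(0.0, sim.noise_sd, size=ab.shape) if sim.noise_sd > 0 else 0.0
    q = np.clip(truth + noise, 0.0, 1.0)
    return list(zip(ab.tolist(), q.tolist()))


def simulate_survival_assay(sim: SimulatedAssay) -> List[Tuple[float, float]]:
    """Survival readouts: binomial surviving fraction per antibody dose.

    At each antibody concentration the true survival probability is the
    complement of the predicted adverse-outcome quotient (sequestration,
    then challenge); the observation is Binomial(n_subjects, p)/n_subjects.
    """
    if sim.challenge is None:
        raise ParameterError("survival simulation requires a challenge model")
    if sim.n_subjects is None or sim.n_subjects < 1:
        raise ParameterError("survival simulation requires n_subjects >= 1")
    if sim.total_agent_conc is None or sim.total_agent_conc < 0:
        raise ParameterError("survival simulation requires total_agent_conc >= 0")
    rng = np.random.default_rng(sim.seed)
    out: List[Tuple[float, float]] = []
    for ab in sim.ab_grid:
        cond = AssayCondition(antibody_conc=float(ab), total_agent_conc=sim.total_agent_conc)
        p_survive = predict_effect_quotient(
            sim.binding, sim.challenge, cond, protective=True
        )
        survivors = int(rng.binomial(sim.n_subjects, p_survive))
        out.append((float(ab), survivors / sim.n_subjects))
    return out


def recover_parameters(
    observations: Sequence[Tuple[float, float]],
    model_form: str = "simple",
    *,
    weighting: str = "entropy",
) -> Tuple[BindingModel, dict]:
    """Refit the binding model to (antibody_conc, q) observations.

    Weighted least squares of the binding isotherm against q on the
    log-concentration scale.  With ``weighting="entropy"`` each residual is
    weighted by sqrt(H(q_observed)), so saturated points (q near 0 or 1)
    are ignored — if no point carries entropy weight the data cannot
    localize the half-maximal response and a :class:`FitError` is raised.
    ``weighting="uniform"`` fits all points equally (for comparison).

    ``model_form`` is "simple" (fit kd only, Hill coefficient fixed at 1)
    or "hill" (fit kd and hill_n jointly).  Returns the fitted model and a
    diagnostics dict (converged, cost, n_used, weights).
    """
    if model_form not in ("simple", "hill"):
        raise ParameterError(f"unknown model_form {model_form!r}")
    if weighting not in ("entropy", "uniform"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    obs = [(a, q) for a, q in observations if a > 0]
    if len(obs) < 3:
        raise FitError("need >= 3 observations at positive antibody concentration")
    ab = np.array([a for a, _ in obs], dtype=float)
    q = np.array([v for _, v in obs], dtype=float)
    if weighting == "entropy":
        w = np.asarray(shannon_entropy(np.clip(q, 0.0, 1.0)), dtype=float)
    else:
        w = np.ones_like(q)
    if not np.any(w > 1e-12):
        raise FitError(
            "all observations are saturated (q near 0 or 1): zero entropy "
            "weight everywhere, the half-maximal response is not localized"
        )
    sw = np.sqrt(w)
    log_ab = np.log(ab)

    # initialize kd at the concentration whose response is nearest half-maximal
    kd0 = float(ab[np.argmin(np.abs(q - 0.5))])

    if model_form == "simple":
        x0 = np.array([np.log(kd0)])

        def resid(theta):
            f = 1.0 / (1.0 + np.exp(theta[0] - log_ab))
            return sw * (f - q)

    else:
        x0 = np.array([np.log(kd0), np.log(1.0)])

        def resid(theta):
            n = np.exp(theta[1])
            f = 1.0 / (1.0 + np.exp(n * (theta[0] - log_ab)))
            return sw * (f - q)

    fit = least_squares(resid, x0, method="lm", max_nfev=10000)
    if not fit.success or not np.all(np.isfinite(fit.x)):
        raise FitError(f"least-squares fit did not converge: {fit.message}")
    kd = float(np.exp(fit.x[0]))
    hill_n = float(np.exp(fit.x[1])) if model_form == "hill" else 1.0
    model = BindingModel(kd=kd, hill_n=hill_n)
    diagnostics = {
        "converged": bool(fit.success),
        "cost": float(fit.cost),
        "n_used": int(len(obs)),
        "weighting": weighting,
        "weights": w.tolist(),
    }
    return model, diagnostics
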