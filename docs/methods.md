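# Methods

## Model and assumptions

The package treats a quantitative antibody-mediated biological effect as
a two-state probability. An observed magnitude *B* relative to its
maximum *B*₀ gives the effect quotient *q* = *B*/*B*₀ ∈ [0, 1]: fractional
loss of antigen activity for inhibition assays (*B*₀ = 1 means complete
inactivation), fractional host survival for challenge assays (*B*₀ = 1
means complete protection). All downstream machinery assumes this
normalization; values outside [0, 1] are rejected by default (see
*Numerical choices*).

Informativeness of an observation is its binary Shannon entropy
*H*(*q*) = −(*q* log₂ *q* + (1 − *q*) log₂(1 − *q*)) in bits. *H* is the
upper bound on the benchmarking weight *w* = *H*(*q*) × quality; the
quality factor (accuracy/precision of the measurement) has no principled
estimator from assay metadata, so it is an opaque caller-supplied scalar
in [0, 1], defaulting to 1.

The benchmark statistic is the weighted Pearson correlation between
observed quotients *X* and predictions *Y* with weighted means
*Z̄* = Σ*wᵢZᵢ*/Σ*wᵢ*. It is invariant under positive affine transforms of
either variable and under rescaling of all weights, and reduces to the
textbook Pearson *r* under uniform weights. Predictions are deliberately
not clipped to [0, 1] before correlation: the statistic is
affine-invariant, so clipping could only destroy information.

Mechanistic forward prediction composes three equilibrium pieces, all
assuming binding pre-equilibration with negligible re-equilibration
during the assay (quasi-equilibrium) and antibody excess over antigen:

1. bound fraction *f* = 1/(1 + (*K_D*/[Ab])ⁿ) — simple isotherm at
   *n* = 1, Hill generalization otherwise. *n* is a real number (it is an
   empirically fitted lower bound on the number of binding sites, not a
   site count).
2. free-agent sequestration *C* = *C*₀/(1 + [Ab]/*K_D*). This is kept in
   its simple non-cooperative form even when the binding model carries
   *n* ≠ 1; a Hill-generalized version would assert cooperative
   sequestration stoichiometry that nothing in the framework constrains.
3. dose-response *p* = 1/(1 + (*C_m*/*C*)ᵇ), with the median effective
   dose *C_m* (LD₅₀/ID₅₀/LC₅₀ by context) and empirical steepness *b*.

Pre-assay dilution is applied by dividing the sequestered free
concentration by the dilution factor before evaluating the dose-response;
that is the only point in the composition where a dilution can act
without also re-shifting the binding equilibrium (which quasi-equilibrium
rules out). Orientation: the composition returns the adverse-outcome
probability by default; `protective=True` returns the complement so
survival-type assays map onto *q* directly. Concentrations must be molar
(or any one consistent unit); assay-specific titer units are rejected
because they are not commensurable across assays.

Two small estimators support dose-shift reasoning: the baseline-to-shifted
median-dose ratio 1 − *f* (an antibody sequestering a fraction *f* of the
agent makes its median effective dose appear larger by 1/(1 − *f*)), and
a provisional EC₅₀ as the geometric mean of two antibody concentrations
bracketing a zero and a maximal response — the natural midpoint of a
serial-dilution titration.

## Curation pipeline

The IEDB reader resolves logical fields through a column map (defaults
are the classic full-format export headers: "BCell ID", "Quantitative
measurement", "Measurement Inequality", "Assay Type Units", …) so header
drift between export versions is a configuration change, not a code
change. Both single-header and two-row grouped-header dialects are
accepted; detection is by attempting resolution on the first header row
and falling back to the second.

Filtering follows the order: optional scope pre-filter (linear-peptide
epitope-as-immunogen records; off by default since exports may be
deliberately broader) → restriction to the 14 antibody-dependent
biological-activity assay types (case-insensitive, whitespace-normalized
matching) → selection of quantitative point estimates. A record survives
selection only with a nonempty numeric measurement and an empty
inequality field; `<`, `>`, `≤`, `≥`, `<=`, `>=` all mark bounds (the
latter four as conservative extensions of the two symbols IEDB uses).
Every exclusion is tallied under its reason, and the tallies partition
the input exactly — this closure is property-tested against the fixture
generator's ground truth.

Quantitative measurements must carry percentage units under the default
strict policy; a lenient flag accepts blank units when the value lies in
[0, 100], with a warning. *B*₀ is taken as 100% throughout (direct
percent-to-fraction conversion). Ranking is by decreasing *q* with ties
broken by ascending BCell ID, which makes the ranked listing
deterministic. Qualitative variants ("Positive-High", "Positive-Low", …)
fold into Positive for the per-assay-type count table; unmappable values
land in an `unclassified` bucket outside the positive/negative sums
rather than silently inflating either.

## Synthetic data

The fixture generator emits IEDB-schema CSVs with exactly known
composition: counts of numeric point estimates, inequality-flagged
bounds, blank measurements, and non-biological-activity records, plus
per-assay-type and positive/negative distributions. It emulates the
schema and the curation-relevant field semantics of real exports — it
does not emulate free-text noise, multi-valued cells, or cross-field
inconsistencies of real curation, so pipeline tests establish rule
correctness, not robustness to arbitrarily dirty data.

Simulated assays come in two flavours. Inhibition: *q* = clip(*f*([Ab]) +
ε, 0, 1) with ε ~ N(0, σ); Gaussian readout noise is a modelling
convention, with σ defaulting to 0.02 as a realistic relative error for a
well-run plate assay. Survival: at each antibody dose the true survival
probability is the complement of the predicted adverse-outcome quotient
and the observation is Binomial(*n*, *p*)/*n* — the sampling model that
"proportion of surviving hosts" dictates. All randomness flows through
explicit integer seeds (numpy `default_rng`); there is no global RNG
state, and outputs are byte-for-byte reproducible.

`recover_parameters` is a validation harness, not a benchmarking
component: it refits *K_D* (and optionally *n*) by least squares of the
isotherm against *q* over log-concentration, weighting residuals by
√*H*(*q*) so saturated observations carry no influence — the same
informativeness logic as the benchmark weights, applied as a loss
weighting. Fitting is in log(*K_D*) (and log *n*) to keep parameters
positive, initialized at the grid point nearest the half-maximal
response, solved with Levenberg-Marquardt. Data with entropy weight
everywhere below 1e-12 raise a fit error: titrations observed only at
saturation cannot localize the half-maximal point.

A caveat established while validating the harness: weighting by the
*observed* entropy is not uniformly better than uniform weighting under
this noise model. Saturated points carry almost no gradient, so at low
noise the two weightings agree to within a few percent (and uniform can
be marginally ahead, because entropy weights computed from noisy
observations couple the noise into the loss). Entropy weighting wins
where it is supposed to: when saturated observations are biased off the
plateau (here, by clamping of the additive noise at the [0, 1]
boundary, material from σ ≈ 0.05), uniform fits absorb that bias and
entropy fits ignore it. The property test pins that regime with fixed
seeds; the methods-level claim is scoped accordingly.

## Numerical choices

- Logistic forms (*f*, *p*) are evaluated as `expit` of the
  log-concentration ratio, which is monotone, overflow-free across
  arbitrary concentration ratios, and exactly ½ at the half point
  ([Ab] = *K_D*, *C* = *C_m*). The zero-concentration limit is defined as
  0 by continuity rather than raising on division.
- Entropy uses `xlogy`, giving the 0·log 0 := 0 convention exactly and
  *H* = 0 at the endpoints and 1 at ½ without rounding residue.
- The "maximal sensitivity at [Ab] = *K_D*" statement is interpreted on
  the log-concentration scale: on a linear scale the isotherm has no
  interior inflection for [Ab] > 0, while d²*f*/d(ln[Ab])² vanishes
  exactly at *K_D*. Tests verify it by central differences (step 1e-3,
  tolerance 1e-6).
- The weighted correlation clamps results to [−1, 1] only to absorb
  last-ulp rounding; zero weighted variance (undefined correlation) and
  all-zero weights (minimally informative dataset) are distinct,
  separately named errors, because they call for different remedies:
  more varied data versus more informative data.
- AUROC uses midranks (Mann-Whitney form), so tied predictions count ½
  and constant predictions score exactly 0.5. Dichotomization labels
  *q* ≥ cutoff positive, cutoff default 0.5, caller-adjustable.
- Out-of-range effects (e.g. >100% inhibition from noise) are errors
  under the default strict policy; an explicit clamp option maps them to
  the nearest endpoint with a warning. Strictness is the default because
  silent clamping would manufacture zero-entropy (hence zero-weight)
  observations.

## Problem sizes

The test suite and the acceptance script use: a 1e-5-step grid (100,001
points) for entropy symmetry/unimodality; 10,000 log-spaced points over
[Ab]/*K_D* ∈ [1e-6, 1e6] for the Hill-vs-simple identity; 1000 random
datasets (n ≤ 40) for wPCC-vs-Pearson agreement; ~1200 random datasets of
size ≤ 8 with tie-heavy scores for AUROC-vs-pair-counting; 100 random
fixture compositions for curation closure; and 50 seeded nine-point
titrations (σ = 0.02, grids spanning ±2 decades around *K_D*) for the
*K_D*-recovery error, reported as a median relative error in percent.
These sizes make every check sharp while keeping the whole suite in the
seconds range on one CPU.

## Known limitations

- Equilibrium only: no kinetic (time-dependent) binding model, and no
  antibody-dependent-enhancement curve (non-monotone enhancement at
  intermediate antibody concentration is out of scope).
- No estimation of *K_D* from antigen structure; affinities are inputs.
- Two-state entropy only; assays with more than two meaningful outcome
  states are not modelled.
- No p-values or confidence intervals for the weighted correlation;
  resampling intervals would be a natural extension.
- Whether "[Ab]" means binding-site or whole-molecule concentration for
  bivalent IgG is the caller's responsibility; the models are agnostic.
- The curation pipeline checks rule correctness against schema-true
  fixtures; it does not attempt source-literature cross-checking of
  curated values, which is human curation work.
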