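# Methods

## Cost model

Total investment per location is `H = fixed + variable` with
`fixed = (P+G+A)/L + B + W·V + R` and `variable = k·(v + n·(t·W + E + D + q))`.
All parameters are technician-hours (counts for `W`); the packaged default
table gives the five method columns (qPCR, goby/fish metabarcoding,
goby/fish seining). Design choices:

- **Currency.** Everything is compared in technician-hours; a helper
  converts at $30/h (2023 technician rate), but no comparison in the
  package runs in dollars.
- **Crew size** `W` enters both the fixed travel term (`W·V`) and the
  per-sample field term (`t·W`), exactly as the equations state. Crew
  composition (e.g. a trained biologist counting as three field workers) is
  the caller's responsibility when setting `W`.
- **Technical replicates.** A per-replicate qPCR cost `r` is carried as a
  field but defaults to 0: at ~$5 per replicate it is negligible, and the
  default `q` for qPCR already folds in three technical replicates per
  sample.
- **Rounding.** Internal arithmetic is unrounded; reports round to 0.1 h.
  The single-sample seining example totals 41.9 h and is quoted as 42 h at
  nearest-hour rounding. Direct evaluation of the equations with the
  default table prices a single metabarcoding sample at 12.0 h
  (7.5 fixed + 4.5 variable); the package asserts only what the equations
  produce.
- **Scenarios** are explicit override objects (e.g. `E→0`, `A→0|8|85`,
  `L→1|10|100`) applied to copies; application is idempotent and validated
  against the known field names.

## Detection model

Detection per sample is Bernoulli; a binomial GLM with logit link on site
and method factors is fitted by maximum likelihood (no regularization),
via statsmodels on an explicitly constructed treatment-coded design matrix.
Per-cell detectability is the inverse logit of the cell's linear predictor;
the 95% CI is a Wald interval on the logit scale mapped through the inverse
logit. Cumulative detection over `n·k` samples is `d = 1−(1−γ)^(n·k)`; CI
endpoints map through the same transform, which is valid because `d` is
monotone in γ — the propagation used for all curve tables (the alternative,
delta-method propagation on the `d` scale, can escape [0, 1]).

- **Complete separation** (a site×method cell all-0 or all-1) is detected
  before fitting; the model still fits (L-BFGS, which tolerates the flat
  likelihood direction), but a `SeparationWarning` is raised and the
  affected estimates are flagged rather than silently reported at an
  extreme value. No Firth-type correction is applied: separated cells are
  meant to be inspected and excluded, not repaired.
- **Rare-case constants.** γ_eDNA = 0.62 (CI 0.42–0.78) shared by qPCR and
  metabarcoding (their detection was statistically indistinguishable where
  both were run), γ_seine = 0.25 (CI 0.12–0.43), from a low-detection site
  (logistic intercept 1.08 − 2.2 site effect; inverse logit 0.246). A
  low-detection site is the right design point: where detection is easy any
  method suffices.
- **Minimal sample count** uses the closed form
  `ceil(log(1−target)/log(1−γ))` with exact integer verification at the
  boundary, since floating-point log ratios can straddle an integer. The
  "confident detection" threshold is taken as d ≥ 0.99.
- Occupancy-style hierarchies (imperfect detection given absence) are out
  of scope: the model conditions on known presence.

## Species accumulation

Collector's curves: for each of `iterations` (default 1,000) random
orderings of the sites, cumulative richness is recorded after each site;
for the single-sample strategy one sample is drawn at random to represent
each site at each iteration (`one_per_site`), and in general `n` samples
are drawn without replacement per site. Read counts reduce to incidence at
≥ 1 read. Medians (used for the headline fit, as is conventional), means
and 5%/95% resampling quantiles are reported per `(n, k)`. A single integer
seed determines all orderings and sample draws, so curves are
bit-reproducible. Tests use 200–4,000 iterations depending on the required
Monte-Carlo tolerance.

The Polce–Kunin model `S = (a + k^z·n^c)/(b + n^c)` is fitted by nonlinear
least squares of `log(model)` against `log(median S)` with all starting
values at 1. Choices:

- **Log scale.** Natural logarithm; the model is logged, not the data
  re-expressed — equivalent to multiplicative errors, which matches how
  richness noise scales. `log_fit=False` switches to a natural-scale fit.
- **Constraints.** `a, b ≥ 0` (trust-region reflective solver), which
  guarantees positive numerator and denominator for `n, k ≥ 1`.
  Unconstrained optimization can drift into a spurious branch where both
  are negative; the constrained region is where the model is meaningful.
- **Diagnostics.** `converged` is set honestly: optimizer failure or a
  Jacobian condition number above 1e8 (e.g. a flat single-site curve, where
  `z` and `c` are unidentifiable) flags the fit with a message instead of
  raising or returning silent garbage. Standard errors come from the
  asymptotic covariance `σ²(JᵀJ)⁻¹` (pseudo-inverse when ill-conditioned);
  prediction CIs use the delta method.
- As `n → ∞` at fixed `k`, predictions approach `k^z`; `z > 0` makes
  predicted richness monotone in sites. Double sampling (`n = 2`) dominates
  single sampling but costs less than twice as much because fixed costs are
  shared — both properties are tested.
- No Chao/ACE estimators or coverage-based rarefaction: only the resampling
  + model-fit route implemented here.

## Consensus taxonomy

Rules, in order: (1) drop ASVs with < 8 total reads; (2) keep only hits at
the ASV's maximum percent identity; (3) reassign hits absent from the
plausible list to their closest plausible relative, formalized as the
maximum shared rank-path depth (class → order → family → genus → species)
against the supplied taxonomy, with alphabetical tie-break, reported in
`reassigned_from`; (4) one surviving candidate → species-rank assignment,
several → their lowest common taxon; (5) the exogenous flag is data-driven
from the habitat column (marine = exogenous), not hard-coded to particular
species. Candidates with no resolvable relative yield an explicit
"unassigned" outcome. The procedure is deterministic.

One documented discrepancy: for a Carassius/Cyprinus tie the supplied
taxonomy's true lowest common taxon is the family Cyprinidae, while the
published community table labels that row at the order rank
(Cypriniformes). The packaged table keeps the printed row label; count
filters classify rows by an explicit rank column, so every published count
is reproduced either way. The packaged table also stores the Fundulus
parvipinnis read figure (printed with ambiguous digit grouping) as 110119;
counts, not reads, drive all checks.

Count modes: `edna_all` counts taxa with positive eDNA reads including
ambiguous-rank and exogenous rows but not "?" (unknown) rows;
`edna_species_rank` restricts to species-rank non-exogenous rows; `seine`
counts captured species ("Visual" rows excluded); the `*_new_reports` modes
additionally require an empty previous-reference field.

## Scenario engine

Curves are emitted as tidy tables (method, scenario, L, k, n, effort, cost
per location, program total, response, CI); plotting is a thin optional
layer so downstream checks never parse images. The grid defaults to the
analysis conditions: assay cost A ∈ {0, 8, 85} h for qPCR, L ∈ {1, 10,
100}, seine variants {full, no_E, no_P_no_E}, k = 1…25, detection curves at
n = 1 sample per site (sites gain more than within-site replicates), and
metabarcoding strategies n ∈ {1, 2}. Crossover summaries report the least
cost at which each curve reaches detection thresholds {0.5, 0.9, 0.95,
0.99} — the set is an implementation choice; 0.99 is the headline
threshold. The cost axis is per-location hours; a program-total column is
also emitted. No budget optimization is attempted: only the enumerated
scenarios.

## Synthetic data

Generators produce schema-valid inputs for every stage, deterministic under
a single integer seed split into named substreams (sites, species, reads),
so enlarging one dimension does not perturb another's draws.

- **Detection records:** independent Bernoulli draws with
  p = inverse-logit(site + method effect) — exactly the GLM's data model.
  Defaults emulate a two-site, two-method design at 20 samples per cell.
- **Community matrices:** each of `pool` species (default 30, comparable to
  an estuarine fish pool) occupies sites at probability `occupancy` (0.6);
  a `turnover` parameter in [0, 1] interpolates between perfectly
  correlated occupancy across sites and independent per-site occupancy, so
  within-site similarity exceeds between-site similarity and fitted `z`
  rises with turnover (verified by simulation contrast). Samples at an
  occupied site detect a species at probability `detection` (0.7). Optional
  read counts are log-normal (log-mean 5, log-sd 2), a heavy-tailed choice
  reflecting read tables spanning ~10 to ~10⁵ reads — a documented default,
  not an inference from data.
- **ASV tables:** constructed to span every consensus rule (sub-threshold
  reads including exactly 7, single plausible hit, implausible hit with a
  unique congener to reassign to, max-identity ties resolving to a genus,
  exogenous-flagged taxa) over a small synthetic taxonomy, with the expected
  assignment embedded per ASV so the consensus procedure is checked
  round-trip against ground truth.

What the generators deliberately do not emulate: sequence-level error (no
FASTQ, PCR or sequencing error models), spatial autocorrelation beyond the
two-level site/sample hierarchy, abundance-driven detectability, or
taxonomic database incompleteness beyond explicit plausibility flags.
Passing tests therefore show the estimators recover the structure they
assume, not that field data satisfy those assumptions.

## Problem sizes in the test suite

Exhaustive-enumeration oracles run on ≤ 4-sample matrices (where all
orderings can be listed); noiseless accumulation-model recovery demands
RSS < 1e-8; noisy recovery uses 200 replicates of 50-point curves at 5%
multiplicative noise (z within ±0.2 in ≥ 90%); GLM calibration uses a
balanced 2×2 design with exactly multiplicative empirical odds (closed-form
check to 1e-6) and 500 simulated datasets at 200 samples per cell (per-cell
95% CI coverage ≥ 93%); the full scenario grid regenerates from scratch in
seconds. The GLM design matrix is built directly (no formula machinery) so
hundreds of refits stay fast.

## Known limitations

- Wald intervals can undercover for cells with few samples or extreme γ;
  profile-likelihood intervals are not implemented.
- The accumulation model is fitted to resampling medians, whose
  step-like discreteness at small richness inflates apparent lack of fit;
  means are reported alongside.
- Replicate-level qPCR detection (within-sample) is not modelled; a
  "sample" is the unit of detection throughout.
- Cost parameters are point estimates; no uncertainty is propagated from
  the cost side of the analysis.
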