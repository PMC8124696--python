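# Methods

## Scope and pipeline

`pmrisk` implements a two-part framework for the risk of a future PM2.5
concentration increase and the choice among mitigation investments:

1. **Risk analysis** — cumulative probability curves per risk factor →
   level probabilities → event tree → consequence distribution →
   conditional risk rating → critical factor.
2. **Decision analysis** — monetary valuation (EMV, exponential EU) of
   mitigation sectors, then multi-criteria scoring with discrete and
   continuous weight-sensitivity analysis.

The packaged LA-LBMA case (`pmrisk.la_lbma_case()`) ships every input needed
to run both parts; all other inputs come from user case files or the
synthetic generators.

## Risk structure

A factor's uncertainty is a CDF over its average annual increase rate,
stored as knots and interpolated **piecewise linearly** — the minimal
assumption when only the curve's shape, not a parametric family, is known.
Level probabilities difference the CDF at the bin edges; since the
interpolated CDF is continuous, the half-open `[lo, hi)` bin convention
(topmost bin closed) matters only for classifying point values, not for
probability mass. Binnings must tile the curve's support; a mismatch larger
than 1e-6 in total mass is an error rather than a silent renormalization.

The elicitation band (lower/upper CDF envelopes) is carried on the curve
object but ignored by all point-estimate operations; only synthetic sampling
uses it.

**Case-study curves.** The published figure for the LA-LBMA factors prints
no knot coordinates. The packaged curves are reconstructions constrained at
the level-bin boundaries so that the High-level marginals implied by the
published conditional-probability table under Bayes' rule are reproduced:
P(population = High) = 0.5 (stated directly), P(economic = High) = 0.7 and
P(temperature = High) = 0.41 (each recovered as
P(High|cons)·P(cons)/P(cons|High) from the printed table entries). They are
labelled `derived` in the case file; no test or reproduction target depends
on their interior shape.

## Event tree and risk rating

Factors are assumed independent, so a joint path's probability is the
product of branch probabilities. Leaves map to consequence categories either
deterministically or via a per-leaf category distribution; enumeration is
exact (≤ dozens of leaves), never sampled. Conditionals in both directions
are computed by restricting and renormalizing the path enumeration; the
inverse direction equals the Bayes formula, which is asserted on generated
trees.

**Verbatim vs reconstructed data.** The published conditional table and
consequence distribution are internally inconsistent: the forward
conditionals admit no valid tree reproducing P(consequence = High) = 0.49
under the law of total probability, and the printed consequence
probabilities sum to 1.007. The case file therefore stores these tables
*verbatim* (the reproduction surface) alongside a clearly-labelled
best-effort reconstructed tree used only for structural demonstrations. The
consequence distribution keeps its printed total, with renormalization
opt-in (`renormalize: false` by default) so downstream numbers match the
published ones. `bayes_invert` accepts mildly inconsistent inputs and clips
a quotient above 1 with a warning instead of failing.

Critical-factor selection is the argmax of P(factor = High | consequence =
High); ties within 1e-12 are reported explicitly and broken by input order.

## Valuation

* Unit conversion: 1 µg = 1e-12 metric ton, so a reduction of Δc µg/m³ over
  V m³ is Δc·V·1e-12 tons. V is symbolic (default 1); every monetary result
  is homogeneous of degree one in V, which is property-tested.
* Scenario monetary value: success probability × $/ton × mass. Benefit
  values per ton are 2010 USD inputs (no inflation adjustment).
* EMV is the scenario-probability-weighted sum of monetary values.
* EU defaults to **per-scenario weighting**: u_i = 1 − exp(−MV_i/R), then
  EU = Σ P_i·u_i. This matches the structure of the published utility table.
  An aggregate mode U(EMV) is also exposed; the two agree to first order for
  small MV/R (asserted at 3 significant figures on the case study for
  R ∈ {5, 100, 200}, and via the limit R·EU → EMV on random problems).
  Utilities use `expm1` for accuracy at small arguments.
* The electricity-generating units alternative carries two scenario
  probability vectors in the source material: an elicited (0.55, 0.40, 0.05)
  and the (0.45, 0.40, 0.15) actually used in the published EMV table. Only
  the latter reproduces the published EMV of 1.37e-7·V, so valuation uses
  it; the elicited vector is kept as metadata and a warning is logged at
  load time.

## MCDA

* Rank bins: half-open `[lo, hi)` with the top bin closed, so touching
  bounds (300, 500, 700 in the investment-efficiency bins) resolve to the
  upper bin. Ordinal criteria map categories to ranks directly.
* Score mapping: `score = max_rank + 1 − rank`. The source tables print
  ranks and scores separately without stating the mapping; this reflection
  is the unique affine map consistent with every printed (rank, score) pair
  (rank 1 → score 4, rank 3 → score 2, …). Criterion direction follows the
  rank tables (smaller $M/ton → rank 1 → highest score) even though the
  prose description of "efficiency" is directionally ambiguous.
* The decision score is affine in the weight vector, so simplex extrema are
  attained at vertices and pairwise preference regions are half-planes.
  `decision_boundary` returns the canonical coefficients of
  DS_a − DS_b = (dS_x − dS_z)x + (dS_y − dS_z)y + dS_z.
* Default simplex grid step 0.01; argmax ties (score gap < 1e-12) are
  reported, never silently broken. On the case-study scorecards, ocean-going
  vessels is the argmax at **every** grid point; its dominance is strict
  everywhere except the single vertex (x, y) = (0, 1) (all weight on
  implementation difficulty), where it ties with electricity-generating
  units at score 3. The refineries/electricity boundary is exactly y = 0.5.

## Synthetic data

The generators produce structurally valid inputs for each stage so that all
properties can be tested without external data: monotone CDFs from sorted
uniform knots with endpoints pinned at 0 and 1 (optional symmetric band),
Dirichlet level/scenario probabilities (concentration 1 by default — uniform
over the simplex), uniform success probabilities, log-uniform $/ton over
$50k–$500k (matching the near-order-of-magnitude spread of real sector
benefit values), and random rank-bin MCDA instances. Default dimensions
mirror the case study (3 factors × 3 levels, 3 alternatives × 3 scenarios,
3 criteria × 4 ranks). Identical seed and configuration give bitwise-identical
output (NumPy `default_rng`).

What the generators do **not** emulate: real demographic or economic
trajectories, correlation between risk factors, PM2.5 chemistry or
dispersion, or elicitation error. Passing property tests therefore
establishes the algebraic and probabilistic correctness of the pipeline, not
the realism of any particular case's inputs.

## Numerical choices

* Probability-sum tolerances 1e-9; conditional/oracle agreement asserted at
  1e-12 where computation is exact arithmetic.
* Division by a zero-probability conditioning event raises
  `UndefinedConditionalError` rather than returning NaN.
* Reported values are rounded to 3 significant figures where tables are
  quoted; full precision is retained internally.
* Validation happens at two layers: dict-level schema checks with
  JSON-pointer-style paths (`decision.alternatives[0].scenario_probability.High:
  1.5 is not a probability`), then type invariants at object construction.

## Known limitations

* The exact event tree behind the published consequence distribution cannot
  be recovered (inconsistent printed conditionals); the reconstructed tree
  is illustrative only.
* The published utility table prints 0 for several small utilities
  (apparent display truncation); only the internally consistent refineries
  column is used as a reference.
* No dependence modelling between risk factors; no fitting of CDFs to
  historical data; monetary values are not inflation-adjusted; no
  AHP/outranking/TOPSIS alternatives to the weighted additive MCDA model.
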