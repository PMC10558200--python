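# Methods

## The individual-sum view of the population attributable fraction

For a single binary risk factor with population prevalence *p* and relative
risk *R* (unexposed baseline risk 1), Levin's formula gives the fraction of
cases attributable to the factor:

    PAF = p(R − 1) / [p(R − 1) + 1].

Multiplying numerator and denominator by the population size *n* rewrites
this as a quotient of two sums over individuals,

    PAF = Σᵢ Aᵢ / Σᵢ Tᵢ,

where Tᵢ is person *i*'s total relative risk given their full exposure
pattern (Tᵢ = 1 for an unexposed person) and Aᵢ = Tᵢ − 1 is their excess.
The value of this reformulation is that it extends to any number of
**correlated** binary factors once a rule is fixed for how co-occurring
factors combine into one total risk. `pafkit` ships two rules and an
extension point:

* **multiplicative** — Tᵢ = Π_j (x_ij R_j − x_ij + 1): joint relative risks
  multiply, so positive clustering of factors *raises* the combined PAF;
* **additive** — Tᵢ = Σ_j x_ij (R_j − 1) + 1: excess risks add.  Summing
  over individuals shows ΣA = n Σ_j p_j (R_j − 1), so the combined additive
  PAF collapses to the prevalence-only form
  Σ p_j (R_j − 1) / [Σ p_j (R_j − 1) + 1] and is *independent of the
  correlation structure*;
* **custom** — any vectorised `combine(pattern, rr)` may be registered.  The
  contract (combine(all-zeros) = 1; a singleton exposure returns its marginal
  RR) is checked at registration and violations raise immediately, because
  both reductions are what make the combined estimate interpretable as a PAF.

Both built-in rules reduce exactly to Levin's formula for one factor, and
with all RR ≥ 1 the multiplicative PAF dominates the additive one on any
data set (term-wise Π ≥ Σ + 1 − k for factors ≥ 1).

For two factors the engine has a closed contingency form: with cell counts
(n₁ both, n₂ x only, n₃ y only, n₄ neither) and a joint RR R_xy,

    PAF = N / (N + n),
    N = n₁(R_xy − R_x − R_y + 1) + (n₁+n₂)(R_x − 1) + (n₁+n₃)(R_y − 1).

R_xy defaults to the interaction rule (R_x·R_y or R_x + R_y − 1) but can be
supplied directly when a study reports the doubly-exposed subgroup's RR;
the result then carries the method label `custom`.

### Protective factors

RRs below 1 produce negative "attributable" terms (prevented fractions).
Mixing these silently into ΣA would corrupt the estimate's interpretation,
so they are rejected by default and accepted only behind
`allow_protective=True`, which also stamps a note into the result.

### Per-factor contributions

The additive model admits an exact split: factor *j* contributes
p_j(R_j − 1) / [Σ p_j(R_j − 1) + 1], and the shares sum to the combined PAF
by construction.  Multiplicative and weighted combinations have no exact
attribution, so the combined total is partitioned proportionally to the
single-factor Levin PAFs.  Both splits are what the package reports and what
the comparison output prints.

## Legacy comparators

Two population-level combinations are implemented for side-by-side
comparison, not as recommended estimators:

* **unweighted multiplicative** (product-complement):
  1 − Π_j (1 − PAF_j).  Equals the individual multiplicative sum exactly
  when the factors' counts are independent (n₁ n = (n₁+n₂)(n₁+n₃)); under
  positive clustering it *understates* the individual-sum value.
* **PCA-communality weighted**: 1 − Π_j (1 − w_j PAF_j) with
  w_j = 1 − communality_j, the communality being factor *j*'s squared
  loadings summed over the principal components of the inter-factor
  tetrachoric correlation matrix retained under the Kaiser rule
  (eigenvalue > 1, strict).  The strictness matters: an identity matrix
  retains *nothing*, all weights are 1, and the method collapses to the
  unweighted one.  Retaining more components can only grow communalities and
  shrink the estimate — the method's sensitivity to an arbitrary retention
  rule is itself one of the behaviours the test suite pins down.
  No rotation is applied to the components.

### Tetrachoric estimation

The correlation behind the weighting is estimated per pair by the standard
two-step: thresholds fixed at the inverse standard normal of the observed
margins, then a bounded 1-D maximum-likelihood search over the latent
correlation ρ ∈ (−0.9999, 0.9999) using bivariate-normal orthant
probabilities (`scipy.stats.multivariate_normal`).  Tables with a zero cell
get a +0.5 continuity correction on every cell first; a zero *margin*
(absent or universal factor) leaves ρ undefined and raises.  Pairwise
estimation does not guarantee a positive semidefinite matrix; by default
indefinite matrices are repaired by clipping negative eigenvalues and
rescaling to unit diagonal (`repair=False` turns this into an error).
The estimator is verified against a brute-force grid-search likelihood
oracle (|Δρ| < 1e-3) and against the closed form available at symmetric
margins (P(both) = 1/4 + arcsin ρ / 2π).

## Bootstrap confidence intervals

The two-step bootstrap treats both the exposure distribution and the
published RRs as uncertain.  Each replicate resamples the *n* rows with
replacement, then draws one RR per factor from
exp(N(log RR, σ)) with σ = (log RR_high − log RR_low) / (2 z₀.₉₇₅), and
re-runs the chosen estimator.  Design choices:

* **one RR vector per replicate**, shared by all rows — the estimand is a
  single population-level RR per factor, not per-person heterogeneity.
  `rr_per_row=True` switches to per-row draws for sensitivity analysis.
* **percentile interval** by default; a normal-approximation interval
  (mean ± z·SD of replicates) is available via `ci_method="normal"`.
* draws below 1 from the lognormal tail are **kept**; truncation would bias
  the interval upward.
* B = 1000 by default; the seed is mandatory, and identical seed + inputs
  give bit-identical replicate vectors.
* for the PCA-weighted estimator the weights are computed once on the
  original sample and held fixed across replicates: re-estimating all
  pairwise tetrachorics per replicate is prohibitively slow and the
  weighting recipe treats them as plug-in constants.

## Synthetic data

The generator draws latent vectors from a multivariate standard normal with
a user-supplied correlation matrix and marks factor *j* present when its
latent coordinate exceeds the (1 − p_j) quantile (exposure on the upper
tail).  The latent correlation is therefore exactly the tetrachoric
correlation of the generated pair, which gives a clean round-trip test with
the estimator above (recovered within ±0.02 at n = 10⁵) and calibrated
margins (within ±0.005 at n = 10⁵).  Thresholding a continuous latent also
makes ties impossible.

What it emulates: marginal prevalences and pairwise latent correlation of
binary exposures.  What it does not: outcome data (the method consumes
exposures and literature RRs only), higher-order dependence beyond the
Gaussian copula, measurement error in exposures, and time-varying exposure.
Passing tests therefore demonstrate the estimators' algebraic and sampling
behaviour, not the causal correctness of any particular published RR set.

`correlated_scenario_pair` builds margin-matched populations at the
independence overlap (n₁ = n p_x p_y) and the maximal overlap
(n₁ = min(n p_x, n p_y)) for studying how clustering moves the
multiplicative PAF (e.g. 0.4041 vs 0.384 at p = (0.2, 0.5), RR = (1.6, 1.9),
n = 10) while the additive PAF stays fixed.

`application_standin` is a fully synthetic 12-factor profile with prevalence
and RR magnitudes typical of published modifiable dementia risk tables and
an exchangeable latent correlation of 0.45, chosen once as a realistic
degree of risk-factor clustering.  On it the methods order as
unweighted multiplicative > additive > PCA-weighted — the qualitative
pattern the individual-sum framework predicts — and that ordering, not any
particular value, is what the tests assert.  n = 5000 is used as a
conservative population-survey scale.

## Numerical choices

* Pure-arithmetic equivalence assertions (contingency vs individual-sum,
  prevalence form vs row-wise sum, single-factor vs Levin) use relative
  tolerance 1e-12; there is no iterative fitting anywhere in the core.
* Tetrachoric ML uses `xatol=1e-6`; orthant probabilities are clipped at
  1e-300 before logs.
* Degenerate RR bounds (low = centre = high) short-circuit to the exact
  centre so σ = 0 bootstraps are bit-exact.
* Eigen-decomposition (not Cholesky) provides the matrix square root in the
  generator, so exactly semidefinite correlation matrices are usable.
* Reports print proportions to 4 significant figures and percentages to
  1 decimal place.

## Known limitations

* Strictly binary exposures; categorical or continuous factors are out of
  scope.
* RRs are assumed causal and constant across individuals; confounded or
  covariate-adjusted RRs bias any Levin-type estimator, and combining
  adjusted RRs additively tends to be conservative.  No adjustment or
  recalibration is attempted.
* No constraint is placed on the accumulated total risk of heavily exposed
  individuals under the multiplicative rule; with many factors Tᵢ can reach
  implausible magnitudes.
* Prevalence uncertainty enters only through row resampling; no analytic
  (delta-method) variance is provided.
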