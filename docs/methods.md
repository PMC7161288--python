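# Methods

This note documents the statistical models, algorithms, defaults and known
limitations of `gllrasch`.  Everything stated here is computed by the code
in this repository; the test suite and `scripts/acceptance.py` reproduce
the behaviour described.

## Models

### Partial Credit model (PCM)

For k ordinal items with categories 0..m_i, the polytomous Rasch (Partial
Credit) model puts

    P(Y_i = y | θ) ∝ exp(α_iy + y·θ),     α_i0 = 0,

so the total score R = Σ Y_i is sufficient for the person parameter θ.
Item thresholds are τ_iy = α_i,y−1 − α_iy and the item location is the
mean threshold −α_im/m.  Identification: the free gauge direction
α_iy → α_iy + c·y (common to all items) is removed by the sum-zero
constraint Σ_i α_i,m_i / m_i = 0, i.e. item locations sum to zero.

### Graphical log-linear Rasch model (GLLRM)

The GLLRM augments the PCM's pattern log-probability with uniform
interaction terms:

* **Local dependence (LD):** λ_ij(y_i, y_j) for declared item pairs, a
  full grid of free cells with corner constraints (any zero index fixes
  the cell at 0).  R remains sufficient for θ.
* **Uniform DIF:** δ_ig(y, c) for declared (item, covariate) pairs, free
  cells for y ≥ 1 and non-reference covariate levels.  Within each
  covariate profile the total score remains sufficient.

"Uniform" is structural: the interaction cells do not depend on θ.

## Conditional estimation

All inference conditions on R (and the DIF covariates), eliminating the
person parameters.  The normalising constants are elementary symmetric
functions γ_r computed **strictly in log space**: LD pairs are merged into
composite components (connected components of the LD graph) whose internal
patterns are enumerated; component score-weight tables are combined by
log-space convolution.  Each covariate profile has its own effective
tables.  This reduction is exact for any model size; the exhaustive
pattern-enumeration oracle is used in the tests to verify agreement to
1e-10 on small instances.

Conditional maximum likelihood uses damped Newton iteration: the gradient
is observed-minus-expected feature counts, and the Hessian is the exact
observed conditional information Σ n_{rc} Cov(features | R=r, profile c),
assembled from component-deleted and pair-of-components-deleted ESF
tables.  The conditional likelihood is concave in this parameterisation;
convergence requires max-norm of the per-person score below 1e-6.
Standard errors are the inverse information at the optimum (verified
against numerical differentiation in the tests).

Degenerate inputs: an item observed in fewer than two categories is an
error; a category never observed (CML cannot identify its parameter) is
collapsed onto the adjacent lower category for estimation and re-expanded
as a flagged non-estimable threshold; interaction cells with zero observed
margin are frozen at 0 with NaN standard errors and excluded from the free
parameter count.

## Diagnostics

* **CLR tests.**  2(Σ_g ℓ̂_g − ℓ̂_pooled), with groups split at the median
  valid total score (ties low; homogeneity/overall fit) or by covariate
  levels (global DIF).  Subgroup fits keep the pooled LD/DIF structure;
  DIF terms on the split covariate are dropped inside its levels
  (absorbed into item parameters).  Degrees of freedom are the sum of
  subgroup free-parameter counts minus the pooled count.  The asymptotic
  χ² reference requires every category populated in every group: with
  sparse cells (rare extreme categories inside a score group) the
  statistic is inflated — verified empirically: null rejection 0.13 at
  nominal 0.05 when the median within-group minimum cell count is ~1,
  0.05 when it is ≥ 6.  `clr_test(..., method="bootstrap")` provides an
  exact conditional bootstrap p (patterns resampled given each person's
  score and profile) for sparse settings.
* **Conditional item fit.**  Residuals against E[Y_i | R, profile] and
  Var[Y_i | R, profile] at the estimates; Outfit = mean standardised
  squared residual, Infit = information-weighted ratio, both with
  expectation 1.  The null distribution is a conditional parametric
  bootstrap (default 400 replicates) given each person's (score, profile);
  each replicate is re-estimated by a one-step Newton update so the null
  carries the same estimation shrinkage as the observed statistic.  The
  two-sided p is the studentised normal probability at the bootstrap mean
  and SE (infit/outfit are means of ~n bounded terms); calibration was
  verified at 0.043/0.023/0.007 empirical rates for nominal
  0.05/0.025/0.01 over 300 null simulations.
* **Kelderman LR screening.**  2(ℓ̂_augmented − ℓ̂_base) for one candidate
  LD pair (df = m_i·m_j) or DIF term (df = m_i·(G−1)); frozen cells reduce
  the df accordingly.  A failed augmented fit is reported as inconclusive,
  never as evidence.
* **Partial Goodman–Kruskal γ.**  γ = (C−D)/(C+D) with the standard
  asymptotic variance; LD effect sizes stratify by each of the two
  restscores (inverse-variance pooling within direction, the headline
  value is the mean of the two directional partial γs, both reported);
  DIF effect sizes stratify by the total score.  Strata with C+D = 0 or
  with perfect association (γ = ±1, zero asymptotic variance — hence
  unbounded inverse-variance weight) are dropped.
* **Benjamini–Hochberg** adjustment via statsmodels, one family per
  screening round per scale.
* **Unidimensionality.**  γ between the two subscale scores (same
  direction, complete cases) versus its expectation under a shared latent
  driver: z ~ N(0,1) is mapped to each subscale's estimated person
  distribution, responses drawn from the fitted models (200,000 simulated
  persons by default), γ computed on the simulated scores.  SE combines a
  person-bootstrap of the observed γ with the Monte Carlo block SE of the
  expectation; the test is one-sided (observed below expected speaks
  against unidimensionality).

## Person-side quantities

* **WML.**  Warm's weighted likelihood estimate maximises
  log P(R=r|θ) + ½ log I(θ) with I(θ) = Var(R|θ); finite at extreme
  scores; SE = 1/√I(θ̂).
* **Person distribution.**  Default: marginal ML — a normal N(μ, σ²) is
  fitted to the observed total-score distribution by Gauss–Hermite
  quadrature over P(R=r|θ).  The WML-moment alternative (mean/SD of WML
  estimates with an SE² correction) is available but biased low in σ by
  WML shrinkage (~15% in simulation), which is why it is not the default.
* **Targeting.**  Test Target Information Index
  = E_θ[I(θ)] / max_θ I(θ); the target score is E[R|θ*] at the
  information maximiser θ*, labelled explicitly as the expected score at
  the θ-maximum.
* **Reliability.**  Cronbach's α for locally independent scales;
  Monte Carlo true-score reliability Var(E[R|θ])/Var(R) from the fitted
  model otherwise (Rao–Blackwellised: conditional moments are analytic
  given simulated θ), per DIF subgroup when DIF is present.  Positive LD
  widens Var(R) without adding true-score variance, so the MC reliability
  sits below α.  Note the *information function* itself is not pointwise
  reduced by LD — the interaction warps and shifts I(θ) — the reduction
  holds for population-averaged information at material λ and for
  reliability/separation.
* **Person separation.**  P(two random persons' scores rank like their
  latent traits), ties in scores counted as half agreement (latent ties
  have probability zero under a normal distribution).
* **DIF score adjustment.**  For each non-reference covariate profile and
  observed score: θ̂ by WML under the subgroup's effective parameters,
  mapped to E[R|θ̂] under the reference profile (including its LD terms);
  reported unrounded with a rounded companion column; the reference
  profile maps to itself.  Adjusted group comparisons report observed
  mean, adjusted mean and bias = observed − adjusted per level.
* **Criterion validity.**  Kendall's τ-b (tie-corrected; Likert scores
  are heavily tied).

## Stepwise item analysis

Per scale: fit the PCM → CLR homogeneity and global DIF → conditional item
fit → Kelderman screening of every admissible LD pair and item×covariate
term, BH-adjusted as one family → add the single most significant
surviving term (ties broken by larger |partial γ|) → refit, repeat.
Exclusion is a last resort and is direction-aware:

* Over-discrimination (infit < 1) is the signature of unmodelled LD and
  never triggers exclusion while candidates remain.
* An item with significant *under*-discrimination (infit > 1) that stays
  significant after a screening-selected term involving it was added is
  judged a poor measure of the trait and excluded — unless a surviving
  DIF candidate still involves it (unmodelled DIF also flattens apparent
  discrimination).
* At the acceptance gate (no surviving candidates), any failing
  asymptotic CLR is first re-checked with the exact conditional bootstrap
  (sparse-cell robustness); acceptance additionally requires no "hard"
  under-discrimination (both statistics significantly above 1 and
  infit > 1.08 — well above the noise band of a conforming item).

The run stops when the CLR tests pass and no screening test survives; an
exhausted exclusion budget yields an explicit "no admissible model", never
a silent pass.  All decisions are logged; identical data, configuration
and seeds reproduce every output byte-for-byte.

## Synthetic data generator

The generator emulates a two-subscale perceived-stress instrument applied
to a general population sample of n = 3857: seven negatively worded items
(raw scores increase with the stress trait) and seven positively worded
items (increase with the control trait); sex (61.9% female) and education
(67.5% tertiary) covariates; five categories per item.

* **Latent traits.**  Bivariate normal drivers with z-correlation −0.955
  (negative because the raw subscales run in opposite directions);
  after reverse-scoring the stress items this realises a between-subscale
  score γ of ≈ 0.53.  Stress: mean −0.55 + 0.26 for women, SD 1.05.
  Control: mean −0.50 + 0.22 for tertiary education, SD 0.80.  The
  subgroup shifts reproduce the direction and rough size of the adjusted
  group differences the package's own analysis then recovers.
* **Thresholds.**  Wide lower steps and clustered hard upper steps
  (stress offsets −3.2, −1.2, 1.9, 2.15; control −2.0, −0.7, 1.3, 1.6
  around per-item locations), so the information function peaks ~2 SD
  above the population mean: mean scores ≈ 8/20 against a target score of
  ≈ 14 (stress).  This mistargeting pattern is a deliberate feature of a
  general-population stress scale; it costs reliability (α ≈ 0.74 for the
  5-item stress subscale) and, as a side effect, makes extreme categories
  rare — which is exactly the regime where the bootstrap CLR matters.
* **LD/DIF.**  Rank-one interactions (λ cells λ0·y_i·y_j, δ cells
  δ0·y·level) so a single scalar per term maps monotonically to a realized
  partial γ.  The scalars are frozen outputs of `calibrate_effect`
  (bisection/secant against two-seed-averaged realized partial γ at
  n = 120,000, verified on an independent seed at n = 200,000; all within
  ±0.01 of the targets 0.18, 0.24, 0.33, −0.14 on the stress side and
  0.22, −0.23, −0.15, −0.17 on the control side).  The fitting side always
  estimates the full unconstrained grids.
* **Misfitting items.**  Generalized partial-credit draws with
  discrimination multipliers a < 1 (0.40–0.72), generation-only, flatten
  the item characteristic curve.  Items 12 and 8 (stress) and 9, 13, 4, 5
  (control) are the deliberate decoys the stepwise analysis should
  exclude.
* **Auxiliary correlates** are monotone transforms of a trait plus noise
  with target Kendall τ set through the normal-score relation; their
  strengths are free configuration parameters.

What the generator does **not** emulate: the survey's multi-stage sampling
design and weights, item-level missingness mechanisms, non-normal trait
distributions, and non-uniform (trait-dependent) LD/DIF.  Passing tests
therefore certify the machinery under clean uniform-GLLRM conditions, not
robustness to those features of real data.

## Problem sizes used by the test suite

Monte Carlo sizes are the package defaults chosen for stable inference:
null calibration of the tests uses 500 simulated datasets (n = 1000,
5 items) with 199 bootstrap replicates per item-fit statistic; power
checks use 100 replicates at n = 3000; parameter-recovery checks use 20
(PCM) and 10 (GLLRM) seeds at n = 3000; effect-size round trips use
n = 200,000; pipeline structure recovery uses 25 replicates at n = 3857.
The null-calibration scenario uses closely spaced thresholds (spread 0.4,
trait SD 0.8) so that every category is well populated within both score
groups — the regularity condition of the asymptotic CLR reference; the
behaviour outside that regime is documented above and covered by the
bootstrap option.

3-SE parameter-recovery checks are asserted as coverage: across a batch
of several hundred z-scores, at most the chance-expected share may exceed
3 SE (nominal exceedance 0.27%) and none may exceed 5 SE.

## Known limitations

* The asymptotic CLR p-values are anti-conservative when extreme
  categories are sparse within score groups; use the bootstrap option
  there (the stepwise pipeline does this automatically at its acceptance
  gate).
* A subscale in which most items under-discriminate (the emulated control
  subscale: 4 decoys of 7 items) is at the edge of what misfit-based
  exclusion can resolve: with a majority of flat items the conforming
  items look over-discriminating relative to the average, and pairwise LD
  terms can absorb much of the departure.  The pipeline resolves the
  stress-type configuration (one or two decoys) reliably; on the control
  configuration it may retain decoys behind extra interaction terms.
* The pooled marginal-ML person distribution treats a DIF-mixed sample as
  one normal; with strong subgroup trait shifts the pooled mean absorbs a
  small bias (use per-profile estimates, as the reliability and targeting
  tables do).
* The generator's trait correlation was calibrated to the observed
  between-subscale γ; the expected-under-unidimensionality γ of the
  emulated instrument (≈ 0.55) is closer to the observed value than in
  the motivating study, so the dimensionality rejection, while in the
  right direction, has a thinner margin.
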