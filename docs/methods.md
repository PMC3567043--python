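# Methods

## Outcome model

For each species, blocks occupied in the first atlas period form the
conditioning set; for those blocks `persisted = 1` if the species was also
recorded in the second period, and `extinct = 1 − persisted`. Presence is
judged under one of two breeding-confidence rules: *any evidence*
(possible, probable or confirmed breeding all count) or *confirmed only*
(the conservative sensitivity scenario). Records are deduplicated to the
highest confidence code per (block, species, period), reflecting atlas
protocols that upgrade codes as evidence accumulates. Because the two
outcomes are exact complements on the same conditioning set, every fit of
the extinction dynamic is the mirror image of the persistence fit; the
implementation preserves this symmetry exactly (below).

The covariate is percent forest cover, on the 0–100 scale, either of the
block itself or averaged over the block plus its eight grid neighbours
(edge and corner blocks average over the neighbours that exist; no
padding or invented cover). Forest percent from a categorical land-cover
grid counts cells of the deciduous, coniferous and mixed forest classes
over all cells of the block footprint; unclassified or missing cells stay
in the denominator, so the figure is cover of the whole block.

## Segmented logistic regression

The threshold model is

    logit p(x) = β₀ + β₁ x + β₂ (x − ψ)₊ ,

fitted by the standard iterative linearization for segmented GLMs: at a
working breakpoint ψ, a logistic model with covariates {x, U, V},
U = (x−ψ)₊, V = −1[x>ψ], is fitted and ψ updated by ψ ← ψ + β_V/β_U; at
convergence β_V ≈ 0 and SE(ψ̂) = SE(β_V)/|β_U| (delta method). Inner
fits use a dedicated IRLS (relative log-likelihood tolerance 1e-10, at
most 100 iterations); the outer loop stops when the update falls below
1e-4 % cover, with at most 50 iterations. AIC uses k = 2 (logistic) and
k = 4 (segmented; the breakpoint counts as a parameter).

Numerical choices, each motivated by a failure mode of the plain
iteration that we observed and verified against a profile-likelihood
oracle:

* **Step-halving with profile acceptance.** Near the optimum the raw
  update oscillates between adjacent inter-datapoint intervals of the
  piecewise-smooth profile likelihood and never meets the tolerance; the
  step is halved until the profile log-likelihood does not deteriorate,
  and the iteration stops when the profile stabilises.
* **Trust region.** The linearization is a first-order local
  approximation; in saturated data regions β_V/β_U is noise, and
  un-damped probes of a huge step amount to a global search. Updates are
  capped at ±5 % cover.
* **Local profile polish.** After convergence, a two-stage profile scan
  (0.25 %-cover grid over ±5, then 0.02 around the leading candidates,
  with a monotone outward march when a winner sits at a window edge and
  a final bounded Brent step) moves the estimate to the local profile
  maximum. The polish is deliberately local: a whole-range scan would
  turn the estimator into a global profile maximiser, which on data with
  no true threshold cherry-picks the best chance kink and overstates the
  evidence for a breakpoint. Global coverage of the start space is the
  job of the multistart wrapper.
* **Quasi-separation.** The IRLS likelihood is evaluated on the clipped
  (±30) linear predictor, so separated inner fits plateau and converge
  with finite estimates instead of failing; species persistent in nearly
  all blocks therefore yield screened, never-selected fits rather than
  crashes.

**Exact complement symmetry.** The IRLS residual, weight and
log-likelihood formulas are written sign-symmetrically (residuals as
expit(−η) for successes and −expit(η) for failures; weights as
expit(η)·expit(−η); log-likelihood as −Σ log(1+e^(−sη)) with s = 2y−1), so
fitting on 1−y reproduces ψ̂, SE(ψ̂) and the log-likelihood bit-for-bit
with all coefficients negated. This structural identity of the model is
preserved exactly, not approximately, and is asserted in the tests.

**Initialization.** A loess smooth of the 0/1 outcome on cover — local
quadratic, tricube weights, span 0.75, no robustifying iterations (on a
binary response they can down-weight every point) — is evaluated on an
even 101-point grid, and the cover at the maximum absolute
finite-difference slope seeds ψ. The search is confined to the 5th–95th
percentile range of the covariate: at the data edges the smooth's
derivative is boundary noise, and an edge initializer sends the
breakpoint into sparse tails it can only overfit. Below 10 observations
the median of x is used, with a warning. When the seeded fit does not
converge, starting values 5, 10, …, 95 % cover (clamped to the data
range) are tried and the converged fit with the highest log-likelihood is
returned; if none converges, a failure report is produced and the species
is reported as non-analysable for that dynamic.

**Profile oracle.** `profile_psi_oracle` fixes ψ on a grid, fits the
logistic model with {x, (x−ψ)₊} at each value, and returns the
log-likelihood curve and its argmax. It shares no code path with the
breakpoint iteration beyond the inner IRLS and serves as the independent
check: on strong-threshold data (slope change 0.5 logit/%, n = 500) the
iterative fit agrees with a 0.25-step oracle within 0.5 % cover on all
50 test seeds, and the oracle's maximum never exceeds the fit's
log-likelihood by more than 1e-4.

## Model selection and screening

The threshold model is selected iff it converged, passes the validity
screen, and the non-threshold model's AIC is more than 2 above it;
otherwise parsimony selects the logistic model, including at a tie. The
screen rejects fits with SE(ψ̂) > 25 % cover (motivated by the gulf in
published tables between accepted fits, SE ≤ ~21, and rejected ones, SE
≈ 143), breakpoints within 2 % cover of the data extremes, and slope
changes below 1e-3 logit/% — the last an automated stand-in for the
visual loess-plot inspection used in practice; all three cutoffs are
configurable and declared in reports, not inferred from any source.
AUC is the rank (Mann–Whitney) statistic of the selected model's fitted
values against the outcomes, computed on the training data; no held-out
validation is attempted, matching field practice, and AUC here measures
discrimination of the fitted curve, not out-of-sample transferability.

## Subsample stability study

From the full pool of per-block outcomes, B subsets of fixed size are
drawn without replacement within each subset and independently across
subsets; both models are refit on each subset and the usual selection
applied. Subsets whose segmented fit fails or is screened out count
toward B but contribute no breakpoint. The selected breakpoints are
summarised by a Gaussian KDE on a 0–100 grid (0.25 steps) with
Silverman's rule-of-thumb bandwidth 0.9·min(σ̂, IQR/1.34)·n^(−1/5) (an
explicit bandwidth can be passed for very small or strongly clustered
samples, where the rule over-smooths), and by the grid mode, ties broken
toward the lowest cover. No boundary correction is applied, so the
density integrates to 1 on the grid only when the breakpoint mass lies
comfortably inside the cover range — true in every study configuration
used here.

## Synthetic data: what it emulates, and what it does not

The generator draws block cover i.i.d. from a Beta distribution rescaled
to [0, 100], parameterised by mean m and concentration κ
(var = m(1−m)/(κ+1) on the proportion scale). Two presets bracket the
study-region archetypes: a Vermont-like region (175 blocks, mean 73.89 %,
κ = 12 — homogeneous high cover) and a New-York-like region (5074 blocks,
mean 63.10 %, κ = 3.5 — wide, left-heavy spread with many low-cover
blocks). Published sources characterise these regions by their means and
histogram shapes only, so κ is calibrated to shape, not to a reported
variance. Occupancy in atlas 1 is a fixed Bernoulli probability,
independent of cover by default, so the conditional persistence curve is
the only cover signal; persistence given occupancy follows the piecewise
logistic with the species' true ψ; breeding-confidence codes are drawn
from a fixed mix. Each (species, seed) pair gets its own RNG stream, so
adding species never perturbs earlier draws.

Canonical effect sizes used in the test suite, chosen once as study
conditions: a *strong* threshold species (intercept −2, slope below 0,
slope change 0.5 logit/% — persistence rises from ~0.12 to ~0.95 within
~6 % cover above ψ = 60), a *moderate* species (slope change 0.25), and a
*null* species (slope change 0, constant persistence ~0.73). The
subsample power analysis uses the strong species on a 3000-block pool.

What the generator does **not** emulate — hence what passing tests do not
establish about real atlases: spatial autocorrelation of cover or of
dynamics (blocks are independent, as the block-spacing argument in the
field assumes); detection error and effort variation (no false absences;
the confidence mix is independent of cover); cover change between atlas
periods; and any relationship between occupancy in atlas 1 and cover.

## Statistical behaviour worth knowing (measured with this package)

* **Delta-method coverage.** At the strong effect (n = 2000) the ±2·SE
  interval covers the true ψ in 50/50 seeds. At the moderate effect the
  estimator still equals the profile-likelihood MLE on every dataset
  (verified against the oracle), but coverage drops to ~88 % with a small
  downward bias of ψ̂ — the known under-coverage of Wald-type breakpoint
  intervals at moderate effects. Profile-likelihood or bootstrap
  intervals would be the remedy; they are out of scope here.
* **Null-data behaviour.** On data with no true threshold the segmented
  fit's likelihood gain over the logistic fit is a "best chance kink"
  statistic: across seeded null datasets its median is below 1 log-unit,
  but individual datasets can carry gains of 3–4 (one test dataset has a
  gain of 1.36 at the true ψ itself, so no estimator can stay below 1
  there), and pure ΔAIC then selects a spurious threshold on roughly one
  dataset in ten. This inherent type-I rate is precisely why the Δi > 2
  rule is paired with the SE/edge/shape screen, and why reports carry the
  screen verdicts alongside the AICs.
* **Local estimation.** With a moderate effect at small n the profile
  likelihood can be multimodal with competing optima several % cover
  apart; a local estimator (this one, like the field's standard tool)
  lands in the basin its initializer selects. The grid multistart
  mitigates but cannot abolish this; the subsample study shows the
  consequence as breakpoint spread across subsets.

## Reported summaries

Cross-region summaries average threshold estimates over the species that
support a threshold in both regions, per dynamic; the SE of the mean uses
the sample (n−1) standard deviation. With a single shared species the SE
is reported as undefined rather than zero. The block-versus-neighbourhood
cover diagnostic is a Spearman rank correlation over blocks carrying both
covariates. Scenario reports (2 confidence rules × 2 covariate scales)
are written separately and never pooled.

## Problem sizes in the test and acceptance runs

Oracle-equivalence and complement-symmetry suites use 50 and 10 datasets
of n = 500; parameter recovery uses 50 datasets of n = 2000; the
subsample study uses B = 200 subsets of 175 blocks from a 3000-block pool
plus a 20-seed comparison of subset sizes 175 vs 1000 at B = 30. The
acceptance script scales these to 20–25 replicates. These sizes were
chosen to give stable Monte-Carlo verdicts at interactive runtimes;
the generator and estimator accept arbitrary sizes.
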