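# atlasthresh

Habitat-threshold analysis of breeding-bird atlas dynamics: segmented
(broken-stick) logistic regression of local persistence and extinction on
percent forest cover, with ΔAIC model selection, AUC validation and a
subsample stability study.

## The problem

Repeated breeding-bird atlases survey a fixed grid of ~25 km² blocks a
couple of decades apart. For a block occupied in the first atlas, a species
either *persists* (detected again in the second atlas) or goes locally
*extinct*. A central question in landscape ecology is whether these
dynamics respond to habitat amount abruptly — is there a critical percent
forest cover ψ below which persistence collapses? — and whether such
thresholds transfer across species and regions (e.g. homogeneous,
high-cover Vermont vs the much larger, more variable New York grid).

`atlasthresh` is for ecologists who want to run this analysis end to end,
and for methodologists who want to probe its statistical behaviour
(breakpoint identifiability, ΔAIC selection error, sample-size effects) on
synthetic data with known truth.

## The model

For a block with forest cover x (percent) occupied in atlas 1, the
probability of the outcome y (persistence, or its complement extinction)
is modelled two ways:

* non-threshold: `logit p(x) = β₀ + β₁x` (ordinary logistic regression,
  k = 2 parameters, AIC = −2ℓ + 4);
* threshold: `logit p(x) = β₀ + β₁x + β₂(x − ψ)₊` (one-breakpoint
  segmented logistic regression, k = 4, AIC = −2ℓ + 8),

where `(·)₊` is the positive part and ψ the breakpoint in percent cover.
ψ is estimated by the iterative linearization for segmented GLMs: refit
with working covariates `U = (x − ψ)₊` and `V = −1[x > ψ]`, update
ψ ← ψ + β_V/β_U until the update vanishes, with SE(ψ̂) = SE(β_V)/|β_U| by
the delta method. A loess smooth (span 0.75, local quadratic) seeds ψ, and
a 5 %-step grid of starting values is tried when the seeded fit fails.

The threshold model is selected only when the non-threshold model carries
Δi = ΔAIC > 2 *and* the fit passes a validity screen (breakpoint SE not
absurdly large, breakpoint away from the data edges, non-negligible slope
change). Fit quality is the rank-based (Mann–Whitney) AUC. A subsample
study (B random subsets of fixed size, both models refit on each)
quantifies how sample size drives threshold detectability, summarising the
selected breakpoints by a Gaussian kernel density and its mode.

## Worked example

Simulate a New-York-like region (wide cover spread) with a species whose
true persistence curve has a breakpoint at ψ = 60 % cover, then fit and
compare both models:

```python
import numpy as np
import atlasthresh as at

profile = at.RegionProfile(name="demo", n_blocks=600, grid_dims=(25, 24),
                           cover_mean=63.1, cover_concentration=3.5)
blocks = at.generate_landscape(profile, seed=11)

species = at.SpeciesResponseSpec(
    species_code="BLBW", psi_true=60.0, intercept=-2.0,
    slope_below=0.0, slope_change=0.5,
)
records = at.simulate_species_dynamics(blocks, species, seed=11)

presence = at.apply_confidence_filter(at.deduplicate_records(records))
outcomes = at.classify_outcomes(presence, "BLBW", blocks)
x = np.array([o.covariate_x for o in outcomes])
y = np.array([o.persisted for o in outcomes], dtype=float)

log_fit = at.fit_logistic(x, y)
seg_fit = at.fit_segmented_grid(x, y)
comp = at.compare_models(log_fit, seg_fit, x=x, y=y)

print(f"blocks occupied in atlas 1: {len(outcomes)}")
print(f"non-threshold model: AIC = {log_fit.aic:.2f}")
print(f"threshold model:     AIC = {seg_fit.aic:.2f}, "
      f"psi = {seg_fit.psi:.2f}% (SE = {seg_fit.psi_se:.2f})")
print(f"selected: {comp.selected} (delta_i = {comp.delta_i:.2f}), AUC = {comp.auc:.2f}")
```

Output:

```
blocks occupied in atlas 1: 600
non-threshold model: AIC = 385.06
threshold model:     AIC = 279.86, psi = 59.61% (SE = 1.27)
selected: threshold (delta_i = 105.20), AUC = 0.95
```

The fitted breakpoint 59.61 % (SE 1.27) recovers the true ψ = 60; the
AIC gap of 105 log-units leaves no doubt about the threshold, and the
selected model discriminates persisting from non-persisting blocks with
AUC 0.95.

The same pipeline is scriptable from the shell: `atlasthresh simulate`,
`cover` (percent forest from a categorical land-cover raster), `fit`,
`subsample` and `report` (the full 2 × 2 scenario matrix of breeding-
confidence rule × covariate scale). Run `atlasthresh --help` for flags.

## Layout

| module | contents |
| --- | --- |
| `atlasthresh.synthetic` | region profiles, landscape + species-dynamics generator |
| `atlasthresh.atlas` | block/detection tables, confidence filters, outcome classifier, CSV I/O |
| `atlasthresh.cover` | class histograms, percent forest per block, 3×3 neighbourhood cover, raster readers |
| `atlasthresh.segmented` | IRLS logistic fit, loess initializer, segmented fit, grid multistart, profile oracle |
| `atlasthresh.selection` | ΔAIC comparison, validity screen, rank-based AUC |
| `atlasthresh.resampling` | subsample study, breakpoint KDE and mode |
| `atlasthresh.reporting` | per-region orchestration, cross-region summaries, scale correlation |
| `atlasthresh.datasets` | published reference threshold/AIC tables for worked examples |

See `docs/methods.md` for the statistical details and design choices.
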