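# Methods

## The question and the measurement

Paired riparian samples — one per bank of a river channel, at each of six
longitudinally ranked sites (1 = downstream/perennial, 6 = upstream/driest)
in each of two catchments, on four visits through a drying season — are
compared by presence/absence dissimilarity. Pitfall catches measure
activity density rather than abundance, so all analysis is occurrence-based:
per-trap counts are summed across the six traps of a bank, then binarized.
Taxa recorded only at genus level are merged into a user-specified single
most-likely species before binarization (leaving them separate would
inflate cross-bank dissimilarity whenever the same population is recorded
at different ranks on the two banks); family-level records are dropped with
a warning. Whole site-visit pairs can be excluded by configuration — the
motivating survey excluded B6-V4 (livestock disturbance) and B3-V4 (a
one-species bank that inflated dissimilarity), and these two exclusions are
the package default.

Each dataset split (all species; macropterous = flight-capable;
brachypterous + polymorphic = limited-flight) partitions the species
columns; rows that lose all their species in a split are retained as empty
assemblages.

## Dissimilarity and its partition

For one pair, with `a` shared and `b`, `c` unique species:
β_sor = (b+c)/(2a+b+c); turnover β_sim = min(b,c)/(a+min(b,c));
nestedness-resultant β_sne = β_sor − β_sim (exact additive partition).
Degenerate pairs: both banks empty → all three undefined (NaN, flagged,
excluded from summaries and models with a logged count); exactly one bank
empty → β_sor = 1 with a `degenerate` flag so such pairs can be dropped by
configuration rather than by a hard-coded rule.

## Null model and standardized effect sizes

The reference distribution holds every sample's richness and every
species' occurrence frequency fixed (rows = samples, columns = species;
"fixed-fixed"). Two samplers are provided:

* **curveball** (default): pick two rows, pool the species held by exactly
  one of them, shuffle, deal back preserving each row's richness. Uniform
  over the fixed-marginal state space; verified against exhaustive
  enumeration of a 4×4 space (chi-square GoF on 10,000 samples).
* **sequential (checkerboard) swap**: flip random 2×2 [[1,0],[0,1]]
  submatrices; rejected draws do not count toward the requested number of
  effective swaps, and an attempt cap returns checkerboard-free matrices
  (e.g. all-ones) unchanged. Counting only effective moves makes the chain
  a jump chain whose stationary mass is proportional to state degree; on
  the enumerated 4×4 space this bias is measurable. The sampler is kept for
  comparability with the swap family, but curveball is the default for
  exactly this reason.

Each of the `n_matrices` (default 999) retained matrices is the endpoint of
an independent chain started from the observed matrix, with default
burn-in 20 × n_rows curveball trades (stationarity is reached by ≈5 × n_rows;
the factor is a safety margin) or 10 × fill effective swaps for the
sequential sampler. Chains are seeded from a master seed via a seed
sequence; ensembles are bit-reproducible and record full provenance.
Marginal conservation is asserted for every retained matrix.

z = (β_obs − null mean)/null SD, with the n−1 SD of the draws; the observed
value is not added to the null distribution. z is undefined (and dropped
from models, with a logged count) when the null SD is zero.

**Structural consequences of fixing both marginals.** Because both row sums
of a pair are conserved, `b` and `c` are affine functions of the shared
count `a` within every randomization — and therefore so are β_sor, β_sim
and β_sne. Two corollaries, both verified numerically to machine precision:
(i) the z-scores of total dissimilarity and of turnover are identical, so
the turnover model necessarily reproduces the total model; (ii) the
nestedness z is the negation of the total z wherever defined, and is
undefined for every pair with equal observed bank richness (its null draws
are identically zero). The nestedness model therefore runs on fewer
observations than the turnover model, and pairwise SES analysis under a
fixed-fixed null cannot separate turnover from total dissimilarity — only
the richness-difference (nestedness) information is genuinely distinct.

## Trend models

z ~ position + visit (both numeric, single slope each) with a random
intercept for every catchment:site unit, fitted by REML (statsmodels
MixedLM; cross-checked against lme4 in the test suite to ~1e-4). Wald t
statistics use residual degrees of freedom (df = n − 3); the method is
recorded in every fit since these p-values are slightly anticonservative
relative to Satterthwaite correction. With only two catchments a separate
catchment-level variance is weakly identified, so the single nested-site
intercept is the default structure.

Boundary handling: after the REML fit, the profiled restricted likelihood
is re-evaluated at zero group variance; if the boundary is at least as
likely (the optimizer can stall short of a boundary optimum), the model is
refit by ordinary least squares, reported with var_random = 0 and a
`singular` flag. A zero-variance fit therefore equals OLS exactly.

R² follows the variance-components convention:
R²M = var_fixed/(var_fixed+var_random+var_residual),
R²C = (var_fixed+var_random)/(same), with var_fixed the n−1 variance of the
fixed-effect predictions.

## Synthetic surveys

The generator emulates the motivating design: 2 catchments × 6 sites ×
2 banks × 4 visits × 6 traps = 576 traps, 96 pooled samples, an 82-species
pool with 53 macropterous / 20 polymorphic / 9 brachypterous species
(64.6/24.4/11.0%). Species occupancy probabilities are Beta-distributed
(shape 0.8, mean = base occupancy 0.13, chosen to match the survey's mean
per-sample richness of ~10.5 of 82 species) so the pool has a realistic
rare-species tail.

Cross-bank structure is a single mechanism: the left bank's occupancy
states are drawn independently; each right-bank state is *copied* from the
left with probability κ_eff, else drawn independently. For limited-flight
species κ_eff = clip(κ + δ·(visit−1) − γ·(position−1)); flight-capable
species always use baseline κ. The gradient is deliberately placed on
connectivity rather than on occupancy: shifting occupancy with position
would change richness, not cross-bank similarity, whereas the measured
statistic is cross-bank similarity itself — this makes truth parameters
directly recoverable from the fitted slopes. Default κ = 0.4 gives β
summaries close to those of real paired-bank carabid data and strongly
negative z intercepts.

Per-trap counts for an occupied bank are plumbing (binarized before
analysis): a total of 1 + Poisson(6·0.8 − 1) individuals is split
multinomially over the six traps. The guaranteed single individual makes
occupancy detection exact, so the κ = 1 limit yields β_sor ≡ 0 — detection
noise is deliberately not modelled.

Scenario presets: `null` (κ=γ=δ=0; calibration and type-I worlds),
`convergence` (δ=0.25 on κ=0.2), `gradient` (γ=0.15 on κ=0.75), and the
constructed worlds `replacement` (right bank = left with an equal number of
species swapped in and out → b = c, pure turnover) and `nested_loss`
(species deleted from one bank only → min(b,c) = 0, pure nestedness), both
with the changed fraction increasing upstream.

What the generator does *not* emulate: detection failure, spatial
autocorrelation among sites, species interactions, seasonal phenology of
individual taxa (the survey's *Pterostichus madidus* wave), or abundance
structure beyond presence. Passing calibration/recovery tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to these real-data features.

## Validation experiments (tests + acceptance script)

* Design arithmetic: 576 traps → 96 samples → 94/92 after the two
  exclusions → 46 pairs.
* β algebra: exact limits, partition additivity to 1e-12, brute-force set
  oracle, scipy Dice cross-check.
* Sampler correctness: marginal conservation everywhere; uniformity on an
  enumerated state space.
* Calibration: under the null scenario (banks independent), pooled
  pair-level z over 20 worlds × 999 draws is ≈ N(0,1).
* Power/type-I: δ = 0.25 convergence is detected (negative limited-flight
  visit slope) in ≥ 80% of worlds; null-scenario slope rejections at ≈ 5%.
* LMM: OLS equivalence at the variance boundary; lme4 agreement; R²
  identities.

Replicate counts (20 worlds) and ensemble size (999) are the package's
standard experiment sizes; they complete in a few minutes on one core.

## Known limitations

* Wald t with residual df, not Satterthwaite/Kenward-Roger.
* The sequential swap's effective-move counting is biased on small state
  spaces (documented above); use curveball unless comparability with
  legacy swap results is required.
* Listwise dropping of undefined nestedness z changes that model's sample
  non-randomly (equal-richness pairs are excluded by construction).
* Position and visit are modelled as linear; a categorical visit contrast
  (e.g. a late-season step change) is outside the default surface.
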