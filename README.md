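# bankbeta

Cross-channel β-diversity analysis for paired-bank community surveys.

A river channel splits the riparian zone into two parallel strips of
habitat. How similar the invertebrate assemblages on the two banks are —
and whether that similarity exceeds chance, weakens upstream along a drying
gradient, or changes through the season — tells you whether the channel is
a barrier to movement, and for whom. `bankbeta` implements that analysis
for trait-stratified presence/absence data (here: carabid wing morphology
as a flight-capability proxy), together with a synthetic survey generator
so the whole pipeline can be exercised, calibrated and power-tested without
field data.

## The statistics

For the left/right bank samples of one site on one visit, with `a` shared
species and `b`, `c` species unique to either bank:

* **Sørensen dissimilarity** β_sor = (b+c)/(2a+b+c), partitioned
  (Baselga-style) into **turnover** β_sim = min(b,c)/(a+min(b,c)) and the
  **nestedness-resultant** remainder β_sne = β_sor − β_sim.
* **Null model:** 999 randomizations of the binary sample × species matrix
  preserving all row sums (sample richness) and column sums (species
  frequency), by curveball trades (default) or checkerboard swaps; the pair
  extraction is repeated on each randomized matrix, giving a standardized
  effect size **z = (β_obs − mean(β_null)) / sd(β_null)**. Negative z: banks
  more similar than chance.
* **Trend models:** z ~ longitudinal position + visit with a random
  intercept per site nested in catchment (REML), reported with marginal and
  conditional R² (fixed-effects share vs fixed+random share of variance).

Datasets are analysed three ways: all species, flight-capable
(macropterous) species, and limited-flight (brachypterous + polymorphic)
species.

## Worked example

Simulate a survey in which limited-flight species lose cross-bank
connectivity upstream (the `gradient` scenario), and run the full pipeline:

```bash
bankbeta run --scenario gradient --seed 7 --n-null 999 --outdir out/
```

prints the per-dataset β summary

```text
       dataset  n      min     mean       sd      max
   all_species 46 0.037037 0.282672 0.141186 0.666667
flight_capable 46 0.000000 0.198816 0.135949 0.750000
limited_flight 46 0.000000 0.434870 0.277428 1.000000
```

and the mixed-model fits, of which the two key rows are:

```text
       dataset component  position_estimate  position_se  position_p
flight_capable     total           0.093289     0.075079    0.220765
limited_flight     total           0.582759     0.097707    0.000000412
```

Read: across the 46 left–right pairs, flight-capable assemblages show no
longitudinal trend in standardized cross-channel dissimilarity (slope 0.09
z per site rank, p = 0.22), while limited-flight assemblages diverge
sharply upstream (slope 0.58, p < 1e-6) — the generator's injected effect,
recovered by the pipeline. All intercepts are strongly negative (banks far
more similar than chance), as expected with nonzero baseline connectivity.

Every stage is persisted in `out/` (`trap_counts.csv`, `beta_pairs.csv`,
`ses.csv`, `trend_fits.csv`, `manifest.json` with seeds and config digest),
and each CLI subcommand (`simulate`, `beta`, `null`, `fit`) can re-run a
stage from those intermediates. Real surveys are analysed the same way by
passing occurrence/metadata/trait CSVs in a YAML config instead of a
scenario (see `bankbeta run --help`); the B6-V4/B3-V4 whole-pair exclusions
of the motivating survey are applied by default and are fully
configurable.

## Layout

| module | responsibility |
|---|---|
| `bankbeta.community` | pooling, taxonomic harmonization, binarization, exclusions, trait splits |
| `bankbeta.beta` | Sørensen pairs, Baselga partition, cross-channel extraction, summaries |
| `bankbeta.nullmodel` | fixed-marginal samplers (numba kernels), ensembles, SES z-scores |
| `bankbeta.trends` | REML mixed models, marginal/conditional R² |
| `bankbeta.synthetic` | trap-level survey generator with tunable connectivity (κ, γ, δ) |
| `bankbeta.pipeline` / `bankbeta.cli` | end-to-end orchestration, provenance, CLI |
| `bankbeta.experiments` | replicated calibration/power experiments |

See `docs/methods.md` for the model assumptions, parameter meanings and
known limitations.
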