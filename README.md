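# toxpisim

Simulation framework for quantifying how missing-data imputation changes
**ToxPi** chemical-prioritization scores and ranks.

## The problem

High-throughput screening programs (ToxCast / Tox21) produce large
chemical × assay matrices of negative-log-transformed AC50 potencies,
where `0` means *tested and inactive* and an empty cell means *never
tested*. Prioritization tools such as the Toxicological Priority Index
(ToxPi) aggregate these matrices into a single score per chemical — and
by default treat untested cells as zeros, i.e. assume inactivity. That
assumption can silently push under-tested chemicals down the priority
list. `toxpisim` lets you measure, by Monte-Carlo simulation, how much a
chosen imputation strategy moves ToxPi scores and priority ranks
relative to that zero-fill default.

For each cell of a design grid — *s* slices × *a* assays per slice ×
imputation method × replicate — the pipeline:

1. samples *s·a* assay columns from a working matrix (all chemicals
   kept) and assigns them to *s* slices of *a* assays;
2. fills the missing cells with one of eight methods: `zero`, `mean`,
   `min`, `max`, `knn`, `binomial`, `lls`, `svd`;
3. computes ToxPi scores and ranks: per-chemical slice sums, min–max
   scaled across chemicals per slice, combined with slice weights
   *w* (equal by default), min–max scaled again, so
   `y_i = minmax( Σ_k w_k · minmax(Σ_{j∈slice k} x_ij) ) ∈ [0, 1]`,
   with rank 1 for the highest score;
4. compares against the baseline (zero-imputed working matrix under its
   natural assay-source slices) with four metrics:
   `RMSE = sqrt( Σ_i (y_i − y_i0)² / m )`, per-chemical rank change
   `r_ij − r_i0`, per-chemical score variance across replicates, and
   Bonferroni-corrected Wilcoxon signed-rank / Bartlett tests.

A synthetic-data generator (low-rank non-negative factor model,
zero-inflation, block assay sources, heterogeneous per-chemical and
per-assay missingness) stands in for the real screening matrix so the
whole pipeline runs and is testable without any download; loaders accept
a real exported matrix (CSV, header row of assay IDs, first column of
chemical IDs, `NA` or empty cell = missing) when you have one.

## Worked example

```python
import numpy as np
from toxpisim import (SyntheticConfig, generate, make_baseline, ImputationConfig,
                      impute, compute_toxpi, sample_scenario_dataset, rmse)
from toxpisim.scenario_engine import ScenarioSpec, scenario_seed

config = SyntheticConfig(n_chemicals=50, n_sources=6,
                         assays_per_source_range=(10, 10), seed=42)
working = generate(config).observed          # masked matrix (truth retained)
baseline = make_baseline(working)            # zero-imputed, source slices

spec = ScenarioSpec(s=5, a=10, method_id="mean", replicate_index=1,
                    seed=scenario_seed(0, 5, 10, "mean", 1),
                    sampling_seed=scenario_seed(0, 5, 10, "@sample", 1))
sampled, slices = sample_scenario_dataset(working, spec)
complete = impute(sampled, "mean", ImputationConfig(), np.random.default_rng(spec.seed))
result = compute_toxpi(complete, slices)

print(f"RMSE vs zero-imputed baseline: "
      f"{rmse(result.overall_score, baseline.overall_score):.4f}")
print(f"mean |rank change|: {np.abs(result.rank - baseline.rank).mean():.2f}")
```

prints

```
RMSE vs zero-imputed baseline: 0.1580
mean |rank change|: 9.84
```

i.e. mean imputation on this 5-slice × 10-assay scenario moves overall
scores by 0.158 RMS (on the [0, 1] score scale) and the average chemical
by about 10 rank positions out of 50, relative to the zero-fill default.

The same experiment end-to-end from the shell:

```sh
toxpisim generate --out working.csv --seed 42
toxpisim run --matrix working.csv --out results/ --seed 0
toxpisim report results/
```

`run` writes `scenarios.csv` (one row per imputed dataset: RMSE, signed
and absolute mean rank change, Bartlett test), `combinations.csv` (one
row per s × a × method cell: RMSE and rank-change ranges, score-variance
summaries, Wilcoxon signed-rank test) and a `manifest.yaml` echoing the
configuration and seeds. Identical configuration and seed give
byte-identical outputs, and each scenario is independently seeded, so
any row can be reproduced in isolation.

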