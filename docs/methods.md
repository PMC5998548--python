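# Methods

## Scope and model

`toxpisim` studies one question: how far do ToxPi chemical-prioritization
scores and ranks move when the missing cells of a chemical × assay
potency matrix are filled by different imputation rules, relative to the
ToxPi default of treating every missing cell as inactive (zero)?

The matrix holds negative-log-transformed AC50 values: non-negative,
unitless, larger = more potent, exactly 0 = tested-inactive. Missingness
(never tested) is a distinct state from 0 end-to-end; loaders reject
negative present values and never conflate `NA` with `0`.

## ToxPi scoring

For a complete matrix under a slice model (a partition of assay columns
into s slices), each chemical's slice score is the sum of its values
over the slice's assays, min–max scaled to [0, 1] across chemicals. The
overall score is the weighted sum of slice scores (equal weights by
default), min–max scaled again. Rank 1 is the highest score; ties take
the minimum (competition) rank, which deliberately keeps tie-induced
rank jumps visible instead of averaging them away.

Two conventions were genuinely open:

* **Per-slice scaling.** Whether slices are scaled before combination is
  not recoverable from the aggregate description "summed ... normalized
  to (0, 1)". The default (`scale_slices=True`) scales per slice, the
  convention of the ToxPi reference implementation; the literal
  alternative (min–max of raw grand sums only) is available as
  `scale_slices=False` and every result records which was used.
* **Degenerate normalization.** A slice or score vector with zero range
  maps to all zeros ("no signal" = minimal activity), avoiding a 0/0.

## Simulation design

The design grid is the full factorial s ∈ {5,10,15,20} ×
a ∈ {1,5,10,15,20,30,50,90,125} × 7 methods × replicates. Materializing
a scenario samples s·a assay columns from the working matrix — without
replacement while s·a does not exceed the available assays, with
replacement beyond that (the grid's corner s·a = 2500 exceeds a
~1100-assay matrix, so pure without-replacement is impossible there) —
and fills slices in draw order, which is equivalent in distribution to
random assignment.

**Seeding.** Every scenario derives two seeds by stable (blake2b) hash
of its coordinates: a *sampling* seed from (master, s, a, replicate) and
a *method* seed from (master, s, a, method, replicate). Sampling
deliberately ignores the method so that all seven methods impute the
same simulated dataset per replicate — that is what makes methods
comparable pairwise and keeps the count of simulated datasets (36,000 at
full scale) separate from the count of imputed datasets (252,000).
Results are therefore independent of execution order and any single
scenario can be re-run in isolation.

The baseline is the zero-imputed working matrix scored under its natural
slice structure (one slice per recorded assay source, a single slice
when sources are unknown). Baseline slice structure affects baseline
normalization, so it is recorded in the manifest.

## Imputation methods

All methods are pure functions of (matrix, config, seed); observed cells
are never modified and outputs are complete.

* `zero`, `mean`, `min`, `max` — constant fills per assay column.
* `knn` — for each missing cell (i, j): Pearson correlation of chemical
  i with every other chemical over pairwise-complete observations of the
  input matrix; neighbours need a defined correlation and an observed
  value in assay j; the imputed value is the mean of the k highest
  correlated neighbours' assay-j values, or 0 when fewer than k qualify
  (the chemical is treated as inactive). k defaults to
  ceil(sqrt(number of assays)); a fixed integer k is configurable. A
  correlation is *defined* only with ≥ 3 pairwise-complete observations
  and non-zero variance in both sub-profiles — two-point correlations
  are always ±1 and carry no information.
* `binomial` — per assay, the response rate p = (#observed > 0)/#observed;
  missing cells become Bernoulli(p) draws in {0, 1}. The method inserts
  dichotomous values into an otherwise continuous column; that oddity is
  inherent to its definition and is kept literal.
* `lls` — local least squares: initialize with assay means; select, once,
  each incomplete assay's k (default 2) predictor assays by |Pearson r|
  on the mean-initialized matrix; iterate intercept + k-predictor
  least-squares refits (fit on chemicals whose target value is observed,
  predict the originally-missing cells) until the mean squared
  difference between successive iterates, over all cells, drops below
  0.001.
* `svd` — iterative low-rank completion: missing cells start at 0; each
  iteration reconstructs from the top-r singular components and
  overwrites only the originally-missing cells, until the mean squared
  change of imputed cells drops below 0.001. The reconstruction rank is
  the method's major under-specification: the default ("auto") keeps the
  smallest rank capturing ≥ 90% of squared singular-value mass at the
  first iteration, capped at min(dims) − 1, and is prominently
  configurable.

### Numerical choices

* **Ties.** Correlations are rounded to 12 decimals before neighbour or
  predictor ranking; remaining ties break toward the lower index.
  Without the rounding, analytically-tied profiles (common in
  zero-inflated data) would be ordered by floating-point summation
  noise, making results depend on the correlation routine used.
* **LLS stability.** The refit map is not a guaranteed contraction:
  mutually-predicting assay pairs can oscillate or diverge
  exponentially. Three guards keep it well-behaved: predictor sets are
  frozen after initialization (re-selecting predictors every iteration
  turns the map into a discrete switching system that failed to converge
  on a majority of small test matrices); regressions with condition
  number > 1e8 fall back to the assay mean for that iteration
  (near-collinear predictors otherwise produce runaway extrapolations);
  and a run that has not converged within `max_iterations` (default 100)
  returns the *first* iterate — the classic non-iterative single-pass
  local least squares solution — with a warning, rather than an
  arbitrary point of a non-convergent orbit.
* **SVD non-convergence** returns the last iterate with a warning; the
  iteration is a soft-impute-style projection and was never observed to
  diverge.
* LLS and SVD predictions may be slightly negative (regression /
  reconstruction overshoot); they are not clipped, and the scoring
  stage's min–max normalization handles them. File round-trips of
  imputed matrices use `allow_negative=True`.

## Evaluation

Per imputed dataset: RMSE between its overall scores and the baseline's
(m chemicals, aligned), per-chemical rank change r_ij − r_i0 (signed and
absolute, summarized per dataset and per chemical across replicates),
and Bartlett's two-sample test of score-variance equality against the
baseline scores (untestable — zero variance in a group — is recorded as
such, not coerced). Per s × a × method combination: per-chemical score
variances across replicates (sample variance, n−1), and a two-sided
Wilcoxon signed-rank test of mean scenario scores vs baseline scores —
zero differences discarded, exact null distribution up to 25 tie-free
non-zero differences, normal approximation with continuity correction
above (at several hundred chemicals the approximation is standard; the
variant used is recorded in the manifest). Significance is
Bonferroni-corrected: the family α (default 0.001) divided by the number
of Wilcoxon comparisons (252 at full scale) or Bartlett comparisons
(252,000 at full scale, one test per imputed dataset).

The printed mean-rank-change formula divides by the replicate count, so
it is implemented as the per-chemical mean over replicates; both signed
and absolute versions are reported, since the signed mean lets opposite
shifts cancel while the absolute mean measures instability.

## Synthetic data generator

The generator emulates the statistical shape of a screening matrix
intersected with a priority list — the features the imputers actually
exploit — without fitting any real release:

* nonzero values `potency_scale · (U V) / (4 r)` with Gamma(2,1) factors
  (U: chemicals × r, V: r × assays) and multiplicative lognormal noise
  `exp(noise_sd · Z)`; the normalisation makes the expected nonzero
  value ≈ `potency_scale`. Low rank gives neighbour- and SVD-based
  imputers real signal; with rank 1 and zero noise, chemical profiles
  are exactly proportional (a tested invariant).
* exact zeros injected as independent Bernoulli(`inactive_fraction`)
  draws, default 0.7 — screening readouts are mostly inactive.
* assays in `n_sources` blocks (default 12 blocks of 14–20).
* missingness: each chemical draws a target fraction uniformly from
  `chem_missing_range` (default (0, 0.9414), the per-chemical span of a
  ToxCast × priority-list working matrix) and has exactly round(t·A)
  cells masked,
  sampled without replacement with probabilities proportional to
  per-assay weights from `assay_missing_range` (default (0.05, 1),
  producing strong per-assay heterogeneity). Masking depends only on
  these design draws, never on values (missing-at-random by design). An
  assay left with no observation has one cell restored (from the
  lowest-target chemical) so column statistics stay defined.
* the pre-masking matrix is always retained, enabling ground-truth
  recovery oracles that are impossible on real data.

Defaults are fixed choices, not estimates; the generator makes no
attempt to match real marginals beyond the documented spans.

### What the synthetic conditions do not show

Real screening matrices differ from the generator in ways that change
the *relative ordering* of imputation methods, so directional findings
under the default synthetic profile should not be read as predictions
for real data:

* Real hit rates among tested readouts are typically far below the 30%
  the default `inactive_fraction=0.7` implies. With sparser activity and
  sparser pairwise overlap, kNN imputes mostly zeros (neighbour means of
  inactive values, plus the <k-neighbours fallback) and therefore tracks
  the zero baseline closely; under the defaults its neighbour means
  track the column means instead, so kNN behaves like mean imputation
  here.
* Per-chemical missingness is drawn *uniformly* over its range, so
  constant-fill methods (max, mean) produce boosts proportional to each
  chemical's missing count, which reorders chemicals; in data where the
  bulk of chemicals share similar missingness, the same fills shift
  scores more uniformly and ranks move less.
* Real missingness is block-structured by technology platform, not
  cell-wise.

The test suite therefore treats oracle equivalence, invariants, design
arithmetic and ground-truth recovery as hard checks, and the
paper-style directional comparisons as a separate suite evaluated under
the fixed default profile (100 chemicals × 200 assays, s ∈ {5,10},
a ∈ {5,20}, 25 replicates) — sizes chosen so the whole suite runs in
minutes on one CPU.

## Known limitations

* The lite profile's 25 replicates give coarse per-combination
  distributions; full-scale runs (1000 replicates) are configuration,
  not code, changes.
* `binomial` imputes on the 0/1 scale regardless of `potency_scale`; if
  you generate data on another scale, its imputed values will be off
  that scale by construction (as the method is defined).
* No stratified assay sampling by source, no figure rendering, no
  model-based/Bayesian imputers.
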