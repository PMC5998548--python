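"""Imputation methods for incomplete chemical x assay potency matrices.

Eight methods, addressed by name through :data:`METHODS` /
:func:`impute`:

``zero``
    The ToxPi default: missing cells become 0 (assume inactivity).
``mean`` / ``min`` / ``max``
    Per-assay column statistics of the observed values.
``knn``
    For each missing cell, the mean of the target-assay values of the k
    chemicals most Pearson-correlated with the incomplete chemical
    (pairwise-complete observations); fewer than k eligible neighbours
    means the chemical is treated as inactive (0).
``binomial``
    Dichotomize each assay's observed readouts (active > 0 vs inactive
    0), estimate the per-assay response rate p_j, and draw imputed cells
    as Bernoulli(p_j) in {0, 1}.
``lls``
    Local least squares: initialize with assay means, then iteratively
    regress each incomplete assay on its k most correlated assays and
    re-predict the originally-missing cells until the mean squared
    change between successive iterates falls below a tolerance.
``svd``
    Iterative low-rank completion: initialize missing cells with 0, then
    repeatedly reconstruct the matrix from its top-rank singular
    components, overwriting only the originally-missing cells, until the
    imputed cells stop moving.

Every method is non-destructive: observed cells are bit-identical in the
output, and the output has no missing cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ChemAssayMatrix

__all__ = [
    "ImputationConfig",
    "METHODS",
    "impute",
    "impute_zero",
    "impute_mean",
    "impute_min",
    "impute_max",
    "impute_knn",
    "impute_binomial",
    "impute_lls",
    "impute_svd",
    "resolve_knn_k",
]

# Pearson correlation between two profiles is considered defined only
# with at least this many pairwise-complete observations (2-point
# correlations are always +/-1 and carry no information).
MIN_PAIRWISE_OBS = 3

# LLS regression systems with a worse condition number than this are
# treated as singular (mean fallback for that iteration).
LLS_MAX_CONDITION = 1e8

# Correlations are rounded to this many decimals before neighbour /
# predictor ranking, so analytically-tied profiles break ties by index
# instead of by floating-point summation noise.
CORRELATION_DECIMALS = 12



@dataclass
class ImputationConfig:
    """Tunable parameters shared by the imputation methods.

    knn_k : int or "auto"
        Neighbour count for kNN; "auto" = ceil(sqrt(number of assays)).
    lls_k : int
        Number of predictor assays for local least squares (default 2).
    lls_tolerance, svd_tolerance : float
        Convergence thresholds on mean squared change (default 0.001).
    svd_rank : int or "auto"
        Reconstruction rank; "auto" keeps the smallest rank capturing
        >= 90% of squared singular-value mass at the first iteration,
        capped at min(matrix dims) - 1.
    max_iterations : int
        Iteration guard for the two iterative methods.
    seed : int
        Random seed for binomial draws when no generator is supplied.
    """

    knn_k: int | str = "auto"
    lls_k: int = 2
    lls_tolerance: float = 0.001
    svd_rank: int | str = "auto"
    svd_tolerance: float = 0.001
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k != "auto" and (not isinstance(self.knn_k, int) or self.knn_k < 1):
            raise ValueError("knn_k must be a positive integer or 'auto'")
        if self.lls_k < 1:
            raise ValueError("lls_k must be >= 1")
        if self.svd_rank != "auto" and (
            not isinstance(self.svd_rank, int) or self.svd_rank < 1
        ):
            raise ValueError("svd_rank must be a positive integer or 'auto'")
        if self.lls_tolerance <= 0 or self.svd_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def resolve_knn_k(config: ImputationConfig | None, n_assays: int) -> int:
    """k for kNN imputation: explicit value, or ceil(sqrt(assay count))."""
    if config is not None and config.knn_k != "auto":
        return int(config.knn_k)
    return math.ceil(math.sqrt(n_assays))


def _require_observed_columns(matrix: ChemAssayMatrix, method: str) -> None:
    dead = np.all(np.isnan(matrix.values), axis=0)
    if dead.any():
        j = int(np.argmax(dead))
        raise ValueError(
            f"{method} imputation requires at least one observed value per assay; "
            f"assay {matrix.assay_ids[j]!r} is 100% missing (filter it first)"
        )


def impute_zero(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
                rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Replace every missing cell with 0 (the ToxPi default)."""
    values = matrix.values.copy()
    values[np.isnan(values)] = 0.0
    return matrix.with_values(values)


def _impute_column_stat(matrix: ChemAssayMatrix, stat, method: str) -> ChemAssayMatrix:
    _require_observed_columns(matrix, method)
    values = matrix.values.copy()
    fill = stat(values, axis=0)
    miss = np.isnan(values)
    values[miss] = np.broadcast_to(fill, values.shape)[miss]
    return matrix.with_values(values)


def impute_mean(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
                rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Replace each missing cell with its assay's observed mean."""
    return _impute_column_stat(matrix, np.nanmean, "mean")


def impute_min(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
               rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Replace each missing cell with its assay's observed minimum."""
    return _impute_column_stat(matrix, np.nanmin, "min")


def impute_max(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
               rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Replace each missing cell with its assay's observed maximum."""
    return _impute_column_stat(matrix, np.nanmax, "max")


def _chemical_correlations(values: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between chemicals (rows).

    Entries are NaN where fewer than MIN_PAIRWISE_OBS pairwise-complete
    observations exist or where either profile has zero variance on the
    shared support.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = pd.DataFrame(values.T).corr(min_periods=MIN_PAIRWISE_OBS).to_numpy()
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.nan)
    return np.round(np.clip(corr, -1.0, 1.0), CORRELATION_DECIMALS)


def impute_knn(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
               rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Neighbour-mean imputation over the k most correlated chemicals.

    Eligible neighbours for cell (i, j) are chemicals with a defined
    correlation to chemical i and an observed value in assay j; the
    imputed value is the mean of the k most correlated eligible
    neighbours' assay-j values. Fewer than k eligible neighbours means
    chemical i is treated as inactive in assay j (imputed 0).
    Correlation ties break toward the lower chemical index.
    """
    values = matrix.values.copy()
    miss = np.isnan(values)
    if not miss.any():
        return matrix.with_values(values)
    k = resolve_knn_k(config, matrix.n_assays)
    corr = _chemical_correlations(matrix.values)

    for j in range(matrix.n_assays):
        miss_rows = np.where(miss[:, j])[0]
        if miss_rows.size == 0:
            continue
        obs_rows = np.where(~miss[:, j])[0]
        col = matrix.values[:, j]
        for i in miss_rows:
            c = corr[i, obs_rows]
            ok = ~np.isnan(c)
            donors = obs_rows[ok]
            if donors.size < k:
                values[i, j] = 0.0
                continue
            order = np.lexsort((donors, -c[ok]))
            values[i, j] = col[donors[order[:k]]].mean()
    return matrix.with_values(values)


def impute_binomial(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
                    rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Bernoulli draws from each assay's observed response rate.

    p_j = (# observed readouts > 0) / (# observed readouts); missing
    cells become 1 with probability p_j, else 0. Observed cells keep
    their continuous values.
    """
    _require_observed_columns(matrix, "binomial")
    if rng is None:
        rng = np.random.default_rng(config.seed if config is not None else 0)
    values = matrix.values.copy()
    miss = np.isnan(values)
    # response rate among *observed* readouts only (NaN > 0 is False, so a
    # plain mean over the comparison would dilute p by the missing cells)
    p = np.where(~miss, values > 0, 0).sum(axis=0) / (~miss).sum(axis=0)
    draws = (rng.random(values.shape) < p[np.newaxis, :]).astype(float)
    values[miss] = draws[miss]
    return matrix.with_values(values)


def _assay_correlation_scores(values: np.ndarray) -> np.ndarray:
    """|Pearson r| between assay columns of a complete matrix; -1 marks undefined."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values, rowvar=False)
    score = np.round(np.abs(corr), CORRELATION_DECIMALS)
    score[~np.isfinite(score)] = -1.0
    np.fill_diagonal(score, -1.0)
    return score


def impute_lls(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
               rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Local least squares imputation.

    Initialized with assay means. Each incomplete assay's k predictor
    assays are selected once, by |Pearson r| on the mean-initialized
    matrix (ties break toward the lower assay index). Each iteration
    then refits, for every assay with originally-missing cells, an
    intercept+k-predictor least-squares regression over chemicals whose
    target value was originally observed, and re-predicts the
    originally-missing cells from the current iterate. Stops when the
    mean squared difference between successive iterates (over all
    cells) drops below ``lls_tolerance``.

    Singular or severely ill-conditioned regression systems (condition
    number above :data:`LLS_MAX_CONDITION`) fall back to the assay's
    observed mean for that iteration; without the conditioning guard,
    near-collinear predictors produce runaway extrapolations.

    The refit map is not a guaranteed contraction: mutually-predicting
    assay pairs can make it oscillate or diverge instead of settling
    below the tolerance. When the iteration has not converged within
    ``max_iterations``, the first iterate — the classic non-iterative
    single-pass local least squares solution — is returned with a
    warning, rather than an arbitrary point of a non-convergent orbit.
    """
    config = config or ImputationConfig()
    _require_observed_columns(matrix, "lls")
    if matrix.n_assays < config.lls_k + 1:
        raise ValueError(
            f"lls requires at least lls_k + 1 = {config.lls_k + 1} assays, "
            f"got {matrix.n_assays}"
        )
    miss0 = np.isnan(matrix.values)
    current = impute_mean(matrix).values
    if not miss0.any():
        return matrix.with_values(current)
    col_mean = np.nanmean(matrix.values, axis=0)
    incomplete_cols = np.where(miss0.any(axis=0))[0]
    k = config.lls_k

    score = _assay_correlation_scores(current)
    predictors: dict[int, np.ndarray] = {}
    for j in incomplete_cols:
        cols = np.delete(np.arange(matrix.n_assays), j)
        order = np.lexsort((cols, -score[cols, j]))
        predictors[j] = cols[order[:k]]

    first_iterate: np.ndarray | None = None
    for iteration in range(config.max_iterations):
        new = current.copy()
        for j in incomplete_cols:
            obs_rows = ~miss0[:, j]
            preds = predictors[j]
            X_obs = np.column_stack([np.ones(obs_rows.sum()), current[obs_rows][:, preds]])
            if obs_rows.sum() < k + 1 or np.linalg.cond(X_obs) > LLS_MAX_CONDITION:
                new[miss0[:, j], j] = col_mean[j]
                continue
            y_obs = matrix.values[obs_rows, j]
            coef, _, _, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
            X_miss = np.column_stack(
                [np.ones(miss0[:, j].sum()), current[miss0[:, j]][:, preds]]
            )
            new[miss0[:, j], j] = X_miss @ coef
        delta = float(np.mean((new - current) ** 2))
        current = new
        if iteration == 0:
            first_iterate = current.copy()
        if delta < config.lls_tolerance:
            break
    else:
        warnings.warn(
            "lls imputation did not converge within max_iterations; "
            "returning the single-pass solution"
        )
        current = first_iterate
    return matrix.with_values(current)


def _auto_svd_rank(singular_values: np.ndarray, n_rows: int, n_cols: int) -> int:
    mass = singular_values**2
    total = mass.sum()
    if total == 0:
        return 1
    cum = np.cumsum(mass) / total
    rank = int(np.searchsorted(cum, 0.9) + 1)
    return max(1, min(rank, min(n_rows, n_cols) - 1))


def impute_svd(matrix: ChemAssayMatrix, config: ImputationConfig | None = None,
               rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Iterative SVD (low-rank) matrix completion.

    Missing cells start at 0; each iteration reconstructs the matrix
    from its top ``svd_rank`` singular components and overwrites only
    the originally-missing cells, stopping once the mean squared change
    of the imputed cells falls below ``svd_tolerance``.
    """
    config = config or ImputationConfig()
    if matrix.n_chemicals < 2 or matrix.n_assays < 2:
        raise ValueError("svd imputation requires at least a 2 x 2 matrix")
    miss0 = np.isnan(matrix.values)
    current = matrix.values.copy()
    current[miss0] = 0.0
    if not miss0.any():
        return matrix.with_values(current)

    rank: int | None = None if config.svd_rank == "auto" else int(config.svd_rank)
    for _ in range(config.max_iterations):
        U, s, Vt = np.linalg.svd(current, full_matrices=False)
        if rank is None:
            rank = _auto_svd_rank(s, *current.shape)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        delta = float(np.mean((recon[miss0] - current[miss0]) ** 2))
        current[miss0] = recon[miss0]
        if delta < config.svd_tolerance:
            break
    else:
        warnings.warn("svd imputation did not converge within max_iterations")
    return matrix.with_values(current)


METHODS = {
    "zero": impute_zero,
    "mean": impute_mean,
    "min": impute_min,
    "max": impute_max,
    "knn": impute_knn,
    "binomial": impute_binomial,
    "lls": impute_lls,
    "svd": impute_svd,
}

#: The seven methods evaluated against the zero-imputed baseline.
EVALUATED_METHODS = ("mean", "min", "max", "knn", "binomial", "lls", "svd")


def impute(matrix: ChemAssayMatrix, method_id: str,
           config: ImputationConfig | None = None,
           rng: np.random.Generator | None = None) -> ChemAssayMatrix:
    """Dispatch to a registered imputation method by name."""
    try:
        fn = METHODS[method_id]
    except KeyError:
        raise ValueError(
            f"unknown imputation method {method_id!r}; valid: {sorted(METHODS)}"
        ) from None
    return fn(matrix, config, rng)
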