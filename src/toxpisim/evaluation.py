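"""Score- and rank-stability metrics against the zero-imputed baseline.

Four metrics and two hypothesis tests compare scenario ToxPi results
with the baseline (the zero-imputed working dataset):

* RMSE between per-chemical overall scores,
  sqrt(sum_i (y_i - y_i0)^2 / m);
* per-chemical rank change r_ij - r_i0 (rank 1 = highest score),
  summarized per chemical as the mean over replicates, both signed and
  in absolute value;
* per-chemical score variance across a combination's replicates
  (sample variance, n-1 denominator);
* Wilcoxon signed-rank test on paired (mean scenario score, baseline
  score) differences, one test per (s, a, method) combination;
* Bartlett's test for equal variances between one scenario's scores and
  the baseline scores, one test per imputed dataset.

Significance is Bonferroni-controlled: per-test alpha =
family alpha / number of comparisons (0.001/252 for Wilcoxon and
0.001/252,000 for Bartlett under the full published design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignificancePolicy",
    "EvaluationRecord",
    "rmse",
    "mean_rank_change",
    "score_variance",
    "wilcoxon_paired",
    "bartlett_variance_test",
    "summarize_combination",
]

#: Largest sample size for which the exact Wilcoxon null distribution is used.
WILCOXON_EXACT_MAX_N = 25


@dataclass
class SignificancePolicy:
    """Bonferroni-corrected significance: per-test alpha = family_alpha / n_comparisons."""

    family_alpha: float = 0.001
    n_comparisons: int = 252

    def __post_init__(self) -> None:
        if not 0 < self.family_alpha <= 1:
            raise ValueError("family_alpha must be in (0, 1]")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")

    @property
    def per_test_alpha(self) -> float:
        return self.family_alpha / self.n_comparisons


@dataclass
class EvaluationRecord:
    """Metrics for one imputed dataset (one scenario replicate)."""

    s: int
    a: int
    method_id: str
    replicate_index: int
    seed: int
    rmse: float
    mean_signed_rank_change: float
    mean_abs_rank_change: float
    bartlett_p: float = float("nan")
    bartlett_significant: bool = False
    bartlett_untestable: bool = False


def _aligned(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vectors are misaligned: shapes {x.shape} vs {y.shape}")
    return x, y


def rmse(scores_sim, scores_ref) -> float:
    """Root mean square error between two aligned per-chemical score vectors."""
    x, y = _aligned(scores_sim, scores_ref)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def mean_rank_change(
    ranks_per_replicate: np.ndarray, ranks_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-chemical mean rank change over replicates, signed and absolute.

    ``ranks_per_replicate`` is an (R, m) table of scenario ranks;
    ``ranks_ref`` the length-m baseline. Returns
    (mean_i over replicates of (r_ij - r_i0),
     mean_i over replicates of |r_ij - r_i0|).
    """
    ranks = np.atleast_2d(np.asarray(ranks_per_replicate, dtype=float))
    ref = np.asarray(ranks_ref, dtype=float)
    if ranks.shape[1] != ref.shape[0]:
        raise ValueError(
            f"replicate ranks have {ranks.shape[1]} chemicals, reference {ref.shape[0]}"
        )
    diff = ranks - ref[np.newaxis, :]
    return diff.mean(axis=0), np.abs(diff).mean(axis=0)


def score_variance(scores_per_replicate: np.ndarray) -> np.ndarray:
    """Per-chemical sample variance (n-1 denominator) across replicates (R >= 2)."""
    table = np.atleast_2d(np.asarray(scores_per_replicate, dtype=float))
    if table.shape[0] < 2:
        raise ValueError("score_variance needs at least 2 replicates")
    return table.var(axis=0, ddof=1)


def wilcoxon_paired(
    mean_scores_sim,
    scores_ref,
    policy: SignificancePolicy,
) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired score differences.

    Zero differences are discarded (classic convention); the exact null
    distribution is used for up to 25 non-zero, tie-free differences,
    the normal approximation with continuity correction otherwise. All
    differences zero is a degenerate test: p = 1, not significant.
    """
    x, y = _aligned(mean_scores_sim, scores_ref)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0, False
    exact = nz.size <= WILCOXON_EXACT_MAX_N and np.unique(np.abs(nz)).size == nz.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            nz,
            zero_method="wilcox",
            correction=not exact,
            alternative="two-sided",
            method="exact" if exact else "approx",
        )
    p = float(res.pvalue)
    return p, p < policy.per_test_alpha


def bartlett_variance_test(
    scores_sim,
    scores_ref,
    policy: SignificancePolicy,
) -> tuple[float, bool]:
    """Two-sample Bartlett test for equal variances (chi-squared, 1 df).

    Raises ValueError when either group has zero variance (untestable).
    The two groups need not be the same length.
    """
    x = np.asarray(scores_sim, dtype=float)
    y = np.asarray(scores_ref, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("bartlett test needs >= 2 values per group")
    if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in a group: bartlett test untestable")
    stat, p = stats.bartlett(x, y)
    p = float(p)
    return p, p < policy.per_test_alpha


def summarize_combination(records: list[EvaluationRecord]) -> dict[str, float]:
    """Range and median summaries of RMSE and rank change for one (s, a, method) cell."""
    if not records:
        raise ValueError("no records to summarize")
    r = np.array([rec.rmse for rec in records])
    signed = np.array([rec.mean_signed_rank_change for rec in records])
    absolute = np.array([rec.mean_abs_rank_change for rec in records])
    first = records[0]
    return {
        "s": first.s,
        "a": first.a,
        "method": first.method_id,
        "n_replicates": len(records),
        "rmse_min": float(r.min()),
        "rmse_median": float(np.median(r)),
        "rmse_max": float(r.max()),
        "rank_change_min": float(signed.min()),
        "rank_change_median": float(np.median(signed)),
        "rank_change_max": float(signed.max()),
        "abs_rank_change_median": float(np.median(absolute)),
        "abs_rank_change_max": float(absolute.max()),
    }
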