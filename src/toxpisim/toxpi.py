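"""ToxPi scoring: slice scores, overall scores on [0, 1], and priority ranks.

The Toxicological Priority Index aggregates a complete chemical x assay
matrix into per-chemical scores. Assays sharing a source ("slice") are
summed per chemical; each slice is min-max scaled to [0, 1] across
chemicals; the weighted combination of slice scores is min-max scaled
again to give the overall score. Rank 1 is the highest-scoring (most
active) chemical; ties receive the minimum (competition) rank.

A degenerate slice or overall vector (all chemicals equal) scales to 0 —
"no signal" reads as minimal activity and avoids division by zero.

``scale_slices=False`` gives the literal alternative reading of the
aggregation (min-max of the raw weighted grand sums only, no per-slice
scaling) for sensitivity checks; every result records which convention
produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ChemAssayMatrix
from .scenario_engine import SliceAssignment

__all__ = ["ToxPiResult", "compute_toxpi", "rank_chemicals", "minmax_scale"]


@dataclass
class ToxPiResult:
    """Per-chemical ToxPi slice scores, overall score in [0, 1], and rank."""

    chemical_ids: list[str]
    slice_scores: np.ndarray  # (n_chemicals, n_slices), each column in [0, 1]
    overall_score: np.ndarray  # (n_chemicals,), in [0, 1]
    rank: np.ndarray  # (n_chemicals,), 1 = highest score
    weights: np.ndarray  # (n_slices,), non-negative, sums to 1
    scale_slices: bool = True


def minmax_scale(v: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def rank_chemicals(scores: np.ndarray) -> np.ndarray:
    """Descending competition ranks: highest score gets rank 1, ties share the minimum rank."""
    return stats.rankdata(-np.asarray(scores, dtype=float), method="min").astype(int)


def compute_toxpi(
    matrix: ChemAssayMatrix,
    slices: SliceAssignment,
    weights: np.ndarray | None = None,
    scale_slices: bool = True,
) -> ToxPiResult:
    """Score and rank the chemicals of a complete matrix under a slice model.

    Parameters
    ----------
    matrix : ChemAssayMatrix
        Complete (no missing cells) matrix whose columns are the slice
        model's assay positions.
    slices : SliceAssignment
        Maps each matrix column to a slice.
    weights : array-like, optional
        Non-negative per-slice weights, not all zero; normalized to sum
        to 1. Default: equal weights.
    scale_slices : bool
        Per-slice min-max scaling before combination (the reference
        ToxPi convention) vs. min-max of raw grand sums only.
    """
    if not matrix.is_complete():
        raise ValueError("compute_toxpi requires a complete matrix; impute first")
    if len(slices.slice_of) != matrix.n_assays:
        raise ValueError(
            f"slice assignment covers {len(slices.slice_of)} positions but the "
            f"matrix has {matrix.n_assays} assays"
        )
    n_slices = slices.n_slices
    if weights is None:
        w = np.full(n_slices, 1.0 / n_slices)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_slices,):
            raise ValueError(f"expected {n_slices} weights, got shape {w.shape}")
        if (w < 0).any():
            raise ValueError("slice weights must be non-negative")
        if w.sum() == 0:
            raise ValueError("slice weights must not all be zero")
        w = w / w.sum()

    raw = np.zeros((matrix.n_chemicals, n_slices))
    for s in range(n_slices):
        raw[:, s] = matrix.values[:, slices.slice_of == s].sum(axis=1)

    scaled = np.column_stack([minmax_scale(raw[:, s]) for s in range(n_slices)])
    combined = (scaled if scale_slices else raw) @ w
    overall = minmax_scale(combined)
    return ToxPiResult(
        chemical_ids=list(matrix.chemical_ids),
        slice_scores=scaled,
        overall_score=overall,
        rank=rank_chemicals(overall),
        weights=w,
        scale_slices=scale_slices,
    )
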