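"""Experimental design grid and per-scenario dataset materialization.

A scenario is one cell of the simulation design: s slices x a assays per
slice x imputation method x replicate. Materializing a scenario samples
s*a assay columns from the working matrix (all chemicals retained) and
assigns them to slices in draw order — the first a draws form slice 0,
the next a slice 1, and so on, which is equivalent in distribution to
random assignment.

Sampling is without replacement while s*a does not exceed the number of
available assays, and with replacement beyond that (the full design
reaches s*a = 2500 columns, more than a ToxCast-scale working matrix
holds, so pure without-replacement sampling is impossible there);
duplicated draws become distinct columns of the simulated dataset.

Each scenario carries its own seed, a stable hash of (master seed, s, a,
method, replicate), so any scenario can be reproduced in isolation and
execution order never affects results.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .data_io import ChemAssayMatrix

__all__ = [
    "ScenarioSpec",
    "SliceAssignment",
    "DEFAULT_S_VALUES",
    "DEFAULT_A_VALUES",
    "scenario_seed",
    "build_design_grid",
    "sample_scenario_dataset",
    "grid_summary",
]

#: Slice counts and assays-per-slice of the full published design.
DEFAULT_S_VALUES = (5, 10, 15, 20)
DEFAULT_A_VALUES = (1, 5, 10, 15, 20, 30, 50, 90, 125)


@dataclass(frozen=True)
class ScenarioSpec:
    """One imputed dataset: design cell coordinates plus private seeds.

    ``sampling_seed`` depends only on (master seed, s, a, replicate), so
    every imputation method sees the same simulated dataset for a given
    replicate — methods multiply the imputed-dataset count, not the
    simulated-dataset count. ``seed`` additionally hashes the method and
    drives any method-internal randomness (binomial draws).
    """

    s: int
    a: int
    method_id: str
    replicate_index: int  # 1-based
    seed: int
    sampling_seed: int

    def __post_init__(self) -> None:
        if self.s < 1 or self.a < 1:
            raise ValueError("s and a must be >= 1")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")

    @property
    def combination(self) -> tuple[int, int, str]:
        return (self.s, self.a, self.method_id)


@dataclass
class SliceAssignment:
    """Sampled assay columns and their slice memberships.

    ``sampled_assay_ids`` holds the original assay IDs in draw order
    (duplicates permitted under with-replacement sampling);
    ``slice_of[p]`` is the slice index of position p.
    """

    sampled_assay_ids: list[str]
    slice_of: np.ndarray

    def __post_init__(self) -> None:
        self.slice_of = np.asarray(self.slice_of, dtype=int)
        if len(self.sampled_assay_ids) != len(self.slice_of):
            raise ValueError("sampled_assay_ids and slice_of lengths differ")

    @property
    def n_slices(self) -> int:
        return int(self.slice_of.max()) + 1 if len(self.slice_of) else 0

    @classmethod
    def single_slice(cls, assay_ids: list[str]) -> "SliceAssignment":
        return cls(list(assay_ids), np.zeros(len(assay_ids), dtype=int))

    @classmethod
    def from_source_labels(cls, assay_ids: list[str], labels: list[str]) -> "SliceAssignment":
        """One slice per distinct source label (order of first appearance)."""
        seen: dict[str, int] = {}
        slice_of = []
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(seen)
            slice_of.append(seen[lab])
        return cls(list(assay_ids), np.array(slice_of, dtype=int))


def scenario_seed(master_seed: int, s: int, a: int, method_id: str, replicate: int) -> int:
    """Stable per-scenario seed in [0, 2^31) derived from the design coordinates."""
    key = f"{master_seed}|{s}|{a}|{method_id}|{replicate}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_design_grid(
    s_values=DEFAULT_S_VALUES,
    a_values=DEFAULT_A_VALUES,
    methods=("mean", "min", "max", "knn", "binomial", "lls", "svd"),
    replicates: int = 1000,
    master_seed: int = 0,
) -> list[ScenarioSpec]:
    """Full factorial design: every (s, a, method) combination x replicates.

    Scenario order is row-major over (s, a, method, replicate) but each
    entry's seed depends only on its own coordinates, so results are
    independent of execution order.
    """
    from .imputation import METHODS  # deferred: avoid import cycle

    if not s_values or not a_values or not methods:
        raise ValueError("s_values, a_values and methods must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid: {sorted(METHODS)}")
    grid = []
    for s in s_values:
        for a in a_values:
            for m in methods:
                for r in range(1, replicates + 1):
                    grid.append(
                        ScenarioSpec(
                            s,
                            a,
                            m,
                            r,
                            seed=scenario_seed(master_seed, s, a, m, r),
                            sampling_seed=scenario_seed(master_seed, s, a, "@sample", r),
                        )
                    )
    return grid


def sample_scenario_dataset(
    matrix: ChemAssayMatrix,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ChemAssayMatrix, SliceAssignment]:
    """Materialize a scenario: sample s*a assay columns, keep all chemicals.

    Output columns get fresh positional IDs (``P0001``...) with the
    original assay IDs recorded in the returned SliceAssignment.
    """
    if matrix.n_assays < 1:
        raise ValueError("matrix has no assays to sample")
    rng = np.random.default_rng(spec.sampling_seed) if rng is None else rng
    n = spec.s * spec.a
    replace = n > matrix.n_assays
    cols = rng.choice(matrix.n_assays, size=n, replace=replace)
    sampled = ChemAssayMatrix(
        list(matrix.chemical_ids),
        [f"P{p + 1:04d}" for p in range(n)],
        matrix.values[:, cols],
    )
    assignment = SliceAssignment(
        sampled_assay_ids=[matrix.assay_ids[c] for c in cols],
        slice_of=np.repeat(np.arange(spec.s), spec.a),
    )
    return sampled, assignment


def grid_summary(grid: list[ScenarioSpec]) -> dict[str, int]:
    """Design arithmetic of a grid: distinct cells and dataset counts.

    ``simulated_datasets`` counts distinct (s, a, replicate) draws —
    every method is applied to the same simulated dataset, so methods do
    not multiply this count — while ``imputed_datasets`` is the total
    number of scenario entries.
    """
    sa = {(g.s, g.a) for g in grid}
    combos = {g.combination for g in grid}
    sim = {(g.s, g.a, g.replicate_index) for g in grid}
    return {
        "sa_combinations": len(sa),
        "method_combinations": len(combos),
        "simulated_datasets": len(sim),
        "imputed_datasets": len(grid),
    }
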