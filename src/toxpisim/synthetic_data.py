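"""Synthetic chemical x assay AC50 matrices with realistic missingness.

The generator emulates the statistical shape of a high-throughput
screening potency matrix intersected with a chemical priority list:

* non-negative values with a large fraction of exact zeros (chemicals
  tested but inactive in an assay);
* assays grouped into source blocks (technology platforms);
* inter-chemical correlation from a low-rank non-negative factor model,
  so that neighbour- and decomposition-based imputers have signal to
  exploit;
* heterogeneous missingness: each chemical gets its own target missing
  fraction and assays differ in how likely they are to be untested.

Values follow ``potency_scale * (U V) / (4 r)`` with Gamma(2,1) factors
``U`` (chemicals x r) and ``V`` (r x assays), multiplied by lognormal
noise ``exp(noise_sd * Z)``; the Gamma-product normalisation makes the
expected nonzero value equal ``potency_scale``. With ``latent_rank=1``
and ``noise_sd=0`` any two chemicals' profiles are exactly proportional.
Inactive readouts are injected as independent Bernoulli(zero) draws.

Masking realizes each chemical's target fraction exactly (up to
rounding): ``round(t_i * n_assays)`` cells per row are masked, sampled
without replacement with probability proportional to per-assay weights
drawn from ``assay_missing_range``. Missingness therefore depends only
on the design draws, never on the values (MAR by design). A paired
pre-masking copy is always retained so imputation accuracy against
ground truth can be measured — something impossible on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .data_io import ChemAssayMatrix, write_matrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_complete_matrix",
           "apply_missingness", "generate", "write_dataset", "read_sidecar"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic matrix generator.

    Defaults describe a screening-library-like matrix: mostly inactive
    readouts (70% exact zeros), nonzero potencies on the scale of
    -log10 AC50 ~ 1, 12 source blocks of 14-20 assays, per-chemical
    missingness spanning roughly (0%, 94%), and strongly heterogeneous
    per-assay missingness (relative masking weights spanning 0.05-1).
    """

    n_chemicals: int = 100
    n_sources: int = 12
    assays_per_source_range: tuple[int, int] = (14, 20)
    latent_rank: int = 5
    inactive_fraction: float = 0.7
    potency_scale: float = 1.0
    noise_sd: float = 0.25
    chem_missing_range: tuple[float, float] = (0.0, 0.9414)
    assay_missing_range: tuple[float, float] = (0.05, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        lo, hi = self.assays_per_source_range
        if not (1 <= lo <= hi):
            raise ValueError("assays_per_source_range must satisfy 1 <= min <= max")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if self.latent_rank > min(self.n_chemicals, self.n_sources * lo):
            raise ValueError(
                "latent_rank exceeds min(n_chemicals, minimum total assays)"
            )
        if not 0.0 <= self.inactive_fraction <= 1.0:
            raise ValueError("inactive_fraction must be in [0, 1]")
        if self.potency_scale <= 0:
            raise ValueError("potency_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("chem_missing_range", "assay_missing_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")


class SyntheticDataset(NamedTuple):
    """A masked observation matrix paired with its complete ground truth."""

    observed: ChemAssayMatrix
    truth: ChemAssayMatrix
    config: SyntheticConfig


def generate_complete_matrix(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> ChemAssayMatrix:
    """Draw a complete (no missing cells) matrix from the factor model.

    Assay IDs are fresh arbitrary identifiers ``A0001..``; chemicals
    ``C0001..``; each assay carries a source label ``S01..`` recorded in
    ``source_labels``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.assays_per_source_range
    sizes = rng.integers(lo, hi + 1, size=config.n_sources)
    n_assays = int(sizes.sum())
    n, r = config.n_chemicals, config.latent_rank
    if r > min(n, n_assays):
        raise ValueError("latent_rank exceeds min(n_chemicals, total assays)")

    U = rng.gamma(2.0, 1.0, size=(n, r))
    V = rng.gamma(2.0, 1.0, size=(r, n_assays))
    values = config.potency_scale * (U @ V) / (4.0 * r)
    if config.noise_sd > 0:
        values = values * np.exp(config.noise_sd * rng.standard_normal(values.shape))
    inactive = rng.random(values.shape) < config.inactive_fraction
    values[inactive] = 0.0

    chem_ids = [f"C{i + 1:04d}" for i in range(n)]
    assay_ids = [f"A{j + 1:04d}" for j in range(n_assays)]
    sources: list[str] = []
    for s, size in enumerate(sizes):
        sources.extend([f"S{s + 1:02d}"] * int(size))
    return ChemAssayMatrix(chem_ids, assay_ids, values, sources)


def apply_missingness(
    matrix: ChemAssayMatrix,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> ChemAssayMatrix:
    """Mask cells of a complete matrix to the configured missingness structure.

    Each chemical i receives a target fraction t_i ~ U(chem_missing_range);
    exactly round(t_i * n_assays) of its cells are masked, chosen without
    replacement with probabilities proportional to per-assay weights
    w_j ~ U(assay_missing_range). If an assay ends up with no observed
    value (and not every chemical's target is 1), one cell is restored —
    from the chemical with the smallest target — so downstream column
    statistics stay defined.
    """
    if not matrix.is_complete():
        raise ValueError("apply_missingness expects a complete matrix")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, m = matrix.values.shape
    t_lo, t_hi = config.chem_missing_range
    w_lo, w_hi = config.assay_missing_range

    targets = rng.uniform(t_lo, t_hi, size=n)
    weights = rng.uniform(w_lo, w_hi, size=m)
    if weights.sum() <= 0:
        weights = np.ones(m)
    p = weights / weights.sum()

    values = matrix.values.copy()
    for i in range(n):
        k = int(round(targets[i] * m))
        if k <= 0:
            continue
        cols = rng.choice(m, size=min(k, m), replace=False, p=p)
        values[i, cols] = np.nan

    if not np.all(targets >= 1.0):
        dead = np.where(np.all(np.isnan(values), axis=0))[0]
        order = np.argsort(targets, kind="stable")
        for j in dead:
            values[order[0], j] = matrix.values[order[0], j]

    return matrix.with_values(values)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a masked matrix together with its pre-masking ground truth."""
    rng = np.random.default_rng(config.seed)
    truth = generate_complete_matrix(config, rng)
    observed = apply_missingness(truth, config, rng)
    return SyntheticDataset(observed=observed, truth=truth, config=config)


def write_dataset(
    dataset: SyntheticDataset, path: str | Path, missing_token: str = "NA"
) -> None:
    """Write the observed matrix plus a key=value sidecar (config, seed, sources).

    The ground-truth matrix is written alongside with a ``.truth.csv``
    suffix.
    """
    path = Path(path)
    write_matrix(dataset.observed, path, missing_token=missing_token)
    write_matrix(dataset.truth, path.with_suffix(".truth.csv"), missing_token=missing_token)
    meta = path.with_suffix(".meta")
    with open(meta, "w", encoding="utf-8") as fh:
        for key, value in asdict(dataset.config).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}={value}\n")
        if dataset.observed.source_labels is not None:
            fh.write("source_labels=" + ",".join(dataset.observed.source_labels) + "\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    """Parse a key=value sidecar written by :func:`write_dataset`."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                out[key] = value
    return out
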