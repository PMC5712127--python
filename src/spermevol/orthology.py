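"""Orthology conservation statistics for a focal protein subset.

Two complementary analyses of how a focal gene set (the sperm proteome)
relates to genome-wide orthology annotations:

* a Yates-corrected 2x2 chi-square comparing sperm-proteome overlap of
  ortholog sets between two reference species, and
* an empirical resampling null for the per-species proportion of focal
  genes with an ortholog, built by repeatedly drawing random gene sets of
  the same size from a background pool and recording their ortholog
  proportion.

Empirical p-values use add-one smoothing, (count + 1) / (n_iter + 1), so
they are never exactly zero; two-sided p doubles the smaller tail, capped
at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OrthologyMatrix:
    """Gene x species ortholog presence with a focal-subset flag.

    ``presence`` is a boolean DataFrame (index gene_id, one column per
    species); ``in_focal`` is a boolean Series on the same index marking
    membership in the focal subset (e.g. the sperm proteome).
    """

    presence: pd.DataFrame
    in_focal: pd.Series

    def __post_init__(self) -> None:
        if self.presence.shape[1] == 0:
            raise ValueError("species list is empty")
        self.in_focal = self.in_focal.reindex(self.presence.index)
        if self.in_focal.isna().any():
            raise ValueError("in_focal flag missing for some genes")
        self.presence = self.presence.astype(bool)
        self.in_focal = self.in_focal.astype(bool)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)


@dataclass
class ResamplingResult:
    species_id: str
    observed_prop: float
    null_props: np.ndarray = field(repr=False)
    p_two_sided: float
    z_score: float | None
    direction: str  # deficit / excess / none


def overlap_chi_square(table, yates: bool = True) -> dict:
    """Chi-square test of homogeneity on a 2x2 count table.

    With ``yates`` (default) the statistic uses the continuity correction
    sum(max(|O - E| - 0.5, 0)^2 / E); otherwise the plain Pearson form.
    The p-value comes from the chi-square distribution with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n == 0:
        raise ValueError("degenerate table: all counts zero")
    expected = row @ col / n
    if (expected == 0).any():
        raise ValueError("degenerate table: an expected cell is zero")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    return {"statistic": statistic, "df": 1, "p": float(stats.chi2.sf(statistic, df=1))}


def _empirical_two_sided(observed: float, null: np.ndarray) -> float:
    n = len(null)
    tail_ge = (int((null >= observed).sum()) + 1) / (n + 1)
    tail_le = (int((null <= observed).sum()) + 1) / (n + 1)
    return min(1.0, 2.0 * min(tail_ge, tail_le))


def resample_null(
    matrix: OrthologyMatrix,
    species_id: str,
    n_iter: int = 5000,
    seed=None,
    pool: str = "non_focal_genes",
    alpha: float = 0.05,
) -> ResamplingResult:
    """Empirical null for the focal subset's ortholog proportion in one species.

    Each iteration draws, without replacement, a gene set the size of the
    focal subset from the chosen pool (``non_focal_genes`` by default, or
    ``all_genes``) and records the proportion of drawn genes with an
    ortholog in ``species_id``. The observed proportion is computed on the
    focal subset and compared against the null by a two-sided add-one
    empirical p-value and a z-score. ``seed`` may be an int or a
    ``numpy.random.Generator``; identical seeds give identical nulls.

    ``direction`` is 'deficit' or 'excess' when p_two_sided < alpha,
    'none' otherwise.
    """
    if species_id not in matrix.presence.columns:
        raise KeyError(f"species {species_id!r} not in matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_iter < 100:
        warnings.warn(
            f"n_iter={n_iter} gives low-resolution empirical p-values "
            f"(floor {1.0 / (n_iter + 1):.3g})",
            stacklevel=2,
        )

    flags = matrix.presence[species_id].to_numpy()
    focal_mask = matrix.in_focal.to_numpy()
    k = int(focal_mask.sum())
    if k < 1:
        raise ValueError("focal subset is empty")
    observed = float(flags[focal_mask].mean())

    pool_flags = flags if pool == "all_genes" else flags[~focal_mask]
    if pool not in ("all_genes", "non_focal_genes"):
        raise ValueError("pool must be 'all_genes' or 'non_focal_genes'")
    n_pool = len(pool_flags)
    if n_pool < k:
        raise ValueError(f"pool ({n_pool} genes) smaller than focal subset ({k})")

    pf = pool_flags.astype(np.float64)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(n_pool, size=k, replace=False)
        null[i] = pf[idx].mean()

    p = _empirical_two_sided(observed, null)
    sd = float(null.std(ddof=1)) if n_iter > 1 else 0.0
    z = (observed - float(null.mean())) / sd if sd > 0 else None
    if p < alpha and z is not None:
        direction = "deficit" if z < 0 else "excess"
    else:
        direction = "none"
    return ResamplingResult(species_id, observed, null, p, z, direction)


def multi_species_report(
    matrix: OrthologyMatrix,
    species_list=None,
    n_iter: int = 5000,
    seed: int = 0,
    pool: str = "non_focal_genes",
) -> list[ResamplingResult]:
    """Run :func:`resample_null` for several species with deterministic substreams.

    A shared master seed spawns one independent random stream per species
    (by species index), so results for one species do not change when
    others are added or removed from the tail of the list.
    """
    species_list = list(species_list) if species_list is not None else matrix.species
    children = np.random.SeedSequence(seed).spawn(len(species_list))
    return [
        resample_null(matrix, sp, n_iter=n_iter, seed=np.random.default_rng(ss), pool=pool)
        for sp, ss in zip(species_list, children)
    ]


def report_table(results) -> pd.DataFrame:
    """Tabulate ResamplingResults (one row per species)."""
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in results],
            "observed_prop": [r.observed_prop for r in results],
            "null_mean": [float(r.null_props.mean()) for r in results],
            "null_sd": [float(r.null_props.std(ddof=1)) if len(r.null_props) > 1 else 0.0 for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
            "z_score": [r.z_score for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("species_id")


def load_matrix(path, delimiter: str = "\t") -> OrthologyMatrix:
    """Read a wide ortholog matrix (gene_id, in_focal, one bool column per species)."""
    df = pd.read_csv(path, sep=delimiter, dtype={"gene_id": str}).set_index("gene_id")
    if "in_focal" not in df.columns:
        raise ValueError("matrix needs an 'in_focal' column")
    return OrthologyMatrix(df.drop(columns="in_focal").astype(bool), df["in_focal"].astype(bool))


def write_matrix(matrix: OrthologyMatrix, path) -> None:
    out = matrix.presence.copy()
    out.insert(0, "in_focal", matrix.in_focal)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
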