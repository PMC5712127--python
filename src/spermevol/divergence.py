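"""Divergence-rate statistics across sperm-proteome strata.

Consumes per-gene nonsynonymous (dN) and synonymous (dS) divergence
estimates from an upstream maximum-likelihood fit and compares their
distributions between gene groups (Lepidoptera-specific sperm proteins,
conserved sperm proteins, genome background) with two-sample
Kolmogorov-Smirnov tests. Rapid evolvers are the top 5% of genes by dN
after Tukey-style removal of extreme outliers (values above
Q3 + 2 * IQR). Synonymous-site saturation is flagged so downstream
comparisons can restrict themselves to dN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

GROUPS = ("lep_specific_sperm", "conserved_sperm", "genome_background")


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n_x: int
    n_y: int


def ks_two_sample(x, y, method: str = "asymp") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over the pooled sample support of the absolute
    difference between the two empirical CDFs (ties are handled by
    evaluating both ECDFs at every pooled point). The p-value uses the
    asymptotic Kolmogorov distribution with effective sample size
    n_x * n_y / (n_x + n_y); ``method='exact'`` delegates the p-value to
    the exact small-sample distribution instead.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("empty sample")
    support = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, support, side="right") / nx
    cdf_y = np.searchsorted(y, support, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = nx * ny / (nx + ny)
    if method == "asymp":
        p = float(special.kolmogorov(np.sqrt(en) * d))
    elif method == "exact":
        p = float(stats.ks_2samp(x, y, method="exact").pvalue)
    else:
        raise ValueError("method must be 'asymp' or 'exact'")
    return KSResult(D=d, p=min(1.0, max(p, 0.0)), n_x=nx, n_y=ny)


def remove_outliers(values, multiplier: float = 2.0) -> dict:
    """Drop values above the upper Tukey fence Q3 + multiplier * IQR.

    Quartiles use linear interpolation between order statistics. Requires
    n >= 4 so quartiles are meaningful. Returns kept and removed values
    (input order preserved) and the fence.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError(f"need >= 4 values to define quartiles, got {len(v)}")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    fence = float(q3 + multiplier * (q3 - q1))
    mask = v > fence
    return {"kept": v[~mask], "removed": v[mask], "fence": fence}


def flag_rapid(table: pd.DataFrame, q: float = 0.95, fence_multiplier: float = 2.0) -> pd.DataFrame:
    """Flag rapidly evolving genes: top (1-q) fraction of dN after outlier removal.

    Outlier fencing and the dN quantile threshold are computed genome-wide
    over the whole table. The threshold is the q-quantile (linear
    interpolation) of the kept dN values and the flag is inclusive
    (dN >= threshold), so ties at the boundary are all flagged. Removed
    outliers are never flagged and carry no percentile rank.

    Returns a DataFrame indexed like ``table`` with columns
    ``is_outlier_removed``, ``is_rapid`` and ``dN_rank_percentile``.
    """
    if len(table) == 0:
        raise ValueError("empty divergence table")
    dn = table["dN"].to_numpy(dtype=float)
    res = remove_outliers(dn, multiplier=fence_multiplier)
    removed_mask = dn > res["fence"]
    kept = dn[~removed_mask]
    threshold = float(np.quantile(kept, q))
    out = pd.DataFrame(index=table.index)
    out["is_outlier_removed"] = removed_mask
    out["is_rapid"] = (~removed_mask) & (dn >= threshold)
    pct = np.full(len(dn), np.nan)
    ranks = stats.rankdata(kept, method="average") / len(kept)
    pct[~removed_mask] = ranks
    out["dN_rank_percentile"] = pct
    return out


def saturation_check(ds, ds_max: float = 3.0) -> dict:
    """Flag synonymous-site saturation.

    Saturated when the median dS reaches ``ds_max`` or at least half the
    genes exceed it (boundary inclusive); saturated data should be
    compared on dN only.
    """
    v = np.asarray(ds, dtype=float)
    if len(v) == 0:
        raise ValueError("empty dS vector")
    med = float(np.median(v))
    frac = float((v > ds_max).mean())
    return {"median_dS": med, "frac_above": frac, "saturated": med >= ds_max or frac >= 0.5}


def stratum_comparison(table: pd.DataFrame, q: float = 0.95) -> dict:
    """Pairwise KS tests of dN between strata plus rapid-evolver proportions.

    ``table`` needs columns ``dN`` and ``group`` (values from
    ``GROUPS``). Returns a dict with a ``ks`` DataFrame (one row per
    pairwise comparison) and a ``rapid`` DataFrame (per-group gene counts
    and the fraction flagged rapid genome-wide). Empty groups are skipped
    with a warning.
    """
    pairs = [
        ("lep_specific_sperm", "conserved_sperm"),
        ("lep_specific_sperm", "genome_background"),
        ("conserved_sperm", "genome_background"),
    ]
    by_group = {g: table.loc[table["group"] == g, "dN"].to_numpy(dtype=float) for g in GROUPS}
    rows = []
    for gx, gy in pairs:
        if len(by_group[gx]) == 0 or len(by_group[gy]) == 0:
            warnings.warn(f"empty group in comparison {gx} vs {gy}; skipped", stacklevel=2)
            continue
        r = ks_two_sample(by_group[gx], by_group[gy])
        rows.append({"group_x": gx, "group_y": gy, "D": r.D, "p": r.p, "n_x": r.n_x, "n_y": r.n_y})
    ks = pd.DataFrame(rows)

    flags = flag_rapid(table, q=q)
    rapid_rows = []
    for g in GROUPS:
        mask = (table["group"] == g).to_numpy()
        kept = mask & ~flags["is_outlier_removed"].to_numpy()
        n_kept = int(kept.sum())
        n_rapid = int((flags["is_rapid"].to_numpy() & mask).sum())
        rapid_rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "n_kept": n_kept,
                "n_rapid": n_rapid,
                "frac_rapid": n_rapid / n_kept if n_kept else float("nan"),
            }
        )
    return {"ks": ks, "rapid": pd.DataFrame(rapid_rows).set_index("group")}


def load_divergence(dn_path, groups_path, delimiter: str = "\t") -> pd.DataFrame:
    """Join a divergence table (gene_id, dN, dS) with stratum assignments.

    Genes missing from either table are dropped; the number dropped is
    attached as ``df.attrs['n_dropped']``.
    """
    dn = pd.read_csv(dn_path, sep=delimiter, dtype={"gene_id": str}).set_index("gene_id")
    gr = pd.read_csv(groups_path, sep=delimiter, dtype={"gene_id": str}).set_index("gene_id")
    if not {"dN", "dS"} <= set(dn.columns):
        raise ValueError("divergence table needs columns dN, dS")
    if "group" not in gr.columns:
        raise ValueError("group table needs a 'group' column")
    joined = dn[["dN", "dS"]].join(gr[["group"]], how="inner")
    joined.attrs["n_dropped"] = len(dn) + len(gr) - 2 * len(joined)
    if (joined[["dN", "dS"]] < 0).any().any():
        raise ValueError("negative divergence estimate")
    return joined
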