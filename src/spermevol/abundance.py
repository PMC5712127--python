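"""Semi-quantitative protein abundance from spectral counts.

Relative abundance follows the APEX estimator: spectral counts n_i are
corrected by per-protein detection probabilities O_i and normalized so the
profile sums to a constant C,

    abundance_i = C * (n_i / O_i) / sum_k (n_k / O_k).

Cross-species conservation of abundance is assessed by ordinary least
squares on log10 abundances of ortholog-matched proteins, and the
direction of differential abundance is tested with an exact one-tail
binomial test against a fair split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DifferentialCall:
    """A differential-abundance call consumed from an upstream count model."""

    protein_id: str
    log_fold_change: float  # positive = higher in the focal species
    adjusted_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjusted_p <= 1.0:
            raise ValueError(f"adjusted_p {self.adjusted_p} outside [0, 1]")


def apex_abundance(counts, probs, C: float = 1.0) -> pd.Series:
    """Detection-probability-corrected relative abundances.

    Parameters
    ----------
    counts
        Mapping or Series protein_id -> spectral count n_i (>= 0; may be
        fractional after correction).
    probs
        Mapping or Series protein_id -> detection probability O_i in (0, 1].
        Every counted protein must have one. Pass ``O_i = 1`` for all
        proteins to fall back to plain normalized spectral counting.
    C
        Normalization constant; the returned profile sums to C.

    Returns
    -------
    pandas.Series of abundances indexed by protein_id.
    """
    counts = pd.Series(dict(counts), dtype=float) if not isinstance(counts, pd.Series) else counts.astype(float)
    probs = pd.Series(dict(probs), dtype=float) if not isinstance(probs, pd.Series) else probs.astype(float)
    if C <= 0:
        raise ValueError("C must be positive")
    if (counts < 0).any():
        raise ValueError("negative spectral count")
    missing = counts.index.difference(probs.index)
    if len(missing):
        raise KeyError(f"no detection probability for: {sorted(missing)[:5]}")
    o = probs.reindex(counts.index)
    if (o <= 0).any() or (o > 1).any():
        raise ValueError("detection probabilities must lie in (0, 1]")
    corrected = counts / o
    total = corrected.sum()
    if total == 0:
        raise ValueError("degenerate profile: all spectral counts are zero")
    out = C * corrected / total
    out.name = "abundance"
    return out


def cross_species_regression(
    profile_a: pd.Series,
    profile_b: pd.Series,
    ortholog_pairs: pd.DataFrame,
    one_to_one_only: bool = True,
) -> dict:
    """OLS fit of log10 abundance between ortholog-matched proteins.

    Both profiles are total-sum normalized, matched through the pair table
    (columns ``id_a``, ``id_b`` and optionally ``one_to_one``), pairs with a
    zero or missing abundance on either side are dropped (``n_dropped``
    reports how many), and log10(b) is regressed on log10(a).

    Returns a dict with R2, slope, intercept, p, n_pairs and n_dropped.
    Raises ``ValueError`` when fewer than 3 usable pairs remain.
    """
    pairs = ortholog_pairs
    if one_to_one_only and "one_to_one" in pairs.columns:
        pairs = pairs[pairs["one_to_one"].astype(bool)]
    a = pd.Series(profile_a, dtype=float)
    b = pd.Series(profile_b, dtype=float)
    a = a / a.sum()
    b = b / b.sum()
    x = a.reindex(pairs["id_a"]).to_numpy()
    y = b.reindex(pairs["id_b"]).to_numpy()
    usable = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    n_dropped = int(len(pairs) - usable.sum())
    x, y = np.log10(x[usable]), np.log10(y[usable])
    if len(x) < 3:
        raise ValueError(f"insufficient data: {len(x)} usable ortholog pairs (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # degenerate regressor or response: no linear signal by convention
        return {"R2": 0.0, "slope": 0.0, "intercept": float(np.mean(y)),
                "p": 1.0, "n_pairs": int(len(x)), "n_dropped": n_dropped}
    fit = stats.linregress(x, y)
    return {
        "R2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p": float(fit.pvalue),
        "n_pairs": int(len(x)),
        "n_dropped": n_dropped,
    }


def direction_bias_test(calls, alpha: float = 0.05) -> dict:
    """Exact binomial test for directional bias among significant calls.

    Counts calls with ``adjusted_p < alpha`` (n_sig) and how many of those
    are up in the focal species (k_up), then computes the one-tail
    probability P(X >= max(k_up, n_sig - k_up)) with X ~ Binomial(n_sig, 1/2).
    """
    n_sig = k_up = 0
    for c in calls:
        if c.adjusted_p < alpha:
            n_sig += 1
            if c.log_fold_change > 0:
                k_up += 1
    if n_sig == 0:
        warnings.warn("no significant calls; direction-bias p reported as 1", stacklevel=2)
        return {"n_sig": 0, "k_up": 0, "p_one_tail": 1.0}
    k = max(k_up, n_sig - k_up)
    p = float(stats.binom.sf(k - 1, n_sig, 0.5))
    return {"n_sig": n_sig, "k_up": k_up, "p_one_tail": min(1.0, p)}


def load_differential_calls(path, delimiter: str = "\t") -> list[DifferentialCall]:
    """Read differential calls (protein_id, log_fold_change, adjusted_p) from TSV."""
    df = pd.read_csv(path, sep=delimiter)
    needed = {"protein_id", "log_fold_change", "adjusted_p"}
    if not needed <= set(df.columns):
        raise ValueError(f"differential table needs columns {sorted(needed)}")
    return [
        DifferentialCall(str(r.protein_id), float(r.log_fold_change), float(r.adjusted_p))
        for r in df.itertuples(index=False)
    ]


def load_profile(path, value_col: str = "abundance", delimiter: str = "\t") -> pd.Series:
    """Read a per-protein value table (protein_id + one value column) as a Series."""
    df = pd.read_csv(path, sep=delimiter, dtype={"protein_id": str},
                     float_precision="round_trip")
    if "protein_id" not in df.columns or value_col not in df.columns:
        raise ValueError(f"profile table needs columns protein_id, {value_col}")
    s = df.set_index("protein_id")[value_col].astype(float)
    if math.isclose(s.sum(), 0.0):
        raise ValueError("profile sums to zero")
    return s
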