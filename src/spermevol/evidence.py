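"""High-confidence proteome construction from replicate MS/MS evidence.

A protein enters the confident sperm proteome if it was identified in two
or more biological replicates, or in a single replicate by two or more
unique peptides, after discarding identifications whose protein-level
probability does not exceed the confidence threshold (default 99%).
Proteins that cannot be distinguished by their peptide evidence are merged
into parsimony groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

EVIDENCE_COLUMNS = (
    "protein_id",
    "replicate_id",
    "unique_peptides",
    "spectral_count",
    "protein_prob",
)


class EvidenceFormatError(ValueError):
    """Raised when an evidence table is structurally malformed."""


@dataclass(frozen=True)
class ReplicateEvidence:
    """One protein identification in one biological replicate.

    Attributes
    ----------
    protein_id : str
        Opaque protein/gene identifier.
    replicate_id : str
        Biological replicate label.
    unique_peptides : int
        Distinct peptides supporting the identification in this replicate.
    spectral_count : int
        Uncorrected peptide-spectrum matches attributed to the protein.
    protein_prob : float
        Protein-level identification probability in [0, 1].
    """

    protein_id: str
    replicate_id: str
    unique_peptides: int
    spectral_count: int
    protein_prob: float


@dataclass
class ProteinCatalog:
    """Per-protein summary of replicate evidence and inclusion status.

    ``table`` is indexed by protein_id with columns ``replicates_detected``,
    ``max_unique_peptides_single_rep``, ``total_spectra`` and ``included``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "replicates_detected",
            "max_unique_peptides_single_rep",
            "total_spectra",
            "included",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")

    @property
    def included_ids(self) -> list[str]:
        return list(self.table.index[self.table["included"]])

    def __len__(self) -> int:
        return len(self.table)


def load_evidence(path, delimiter: str = "\t") -> list[ReplicateEvidence]:
    """Read a delimited evidence table into validated records.

    The table must carry a header naming the five canonical columns
    (extra columns are ignored). Raises :class:`EvidenceFormatError` for a
    missing column and ``ValueError`` (row-indexed) for out-of-range values.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"protein_id": str, "replicate_id": str})
    for col in EVIDENCE_COLUMNS:
        if col not in df.columns:
            raise EvidenceFormatError(f"evidence table missing column {col!r}")
    records: list[ReplicateEvidence] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        up, sc, prob = int(row.unique_peptides), int(row.spectral_count), float(row.protein_prob)
        if up < 0 or sc < 0:
            raise ValueError(f"row {i}: negative count (unique_peptides={up}, spectral_count={sc})")
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"row {i}: protein_prob {prob} outside [0, 1]")
        key = (str(row.protein_id), str(row.replicate_id))
        if key in seen:
            raise ValueError(f"row {i}: duplicate (protein_id, replicate_id) pair {key}")
        seen.add(key)
        records.append(ReplicateEvidence(key[0], key[1], up, sc, prob))
    return records


def filter_confident(
    evidence: Iterable[ReplicateEvidence], min_protein_prob: float = 0.99
) -> list[ReplicateEvidence]:
    """Keep identifications whose probability strictly exceeds the threshold."""
    return [e for e in evidence if e.protein_prob > min_protein_prob]


def apply_inclusion_filter(evidence: Iterable[ReplicateEvidence]) -> ProteinCatalog:
    """Summarize evidence per protein and apply the inclusion criteria.

    A protein is included iff it was detected in >= 2 replicates, or by
    >= 2 unique peptides within some single replicate. Evidence should
    already be probability-filtered (:func:`filter_confident`).
    """
    rows: dict[str, dict] = {}
    for e in evidence:
        r = rows.setdefault(
            e.protein_id,
            {"replicates": set(), "max_up": 0, "total_spectra": 0},
        )
        r["replicates"].add(e.replicate_id)
        r["max_up"] = max(r["max_up"], e.unique_peptides)
        r["total_spectra"] += e.spectral_count
    table = pd.DataFrame(
        {
            "replicates_detected": {p: len(r["replicates"]) for p, r in rows.items()},
            "max_unique_peptides_single_rep": {p: r["max_up"] for p, r in rows.items()},
            "total_spectra": {p: r["total_spectra"] for p, r in rows.items()},
        }
    ).sort_index()
    table.index.name = "protein_id"
    table["included"] = (table["replicates_detected"] >= 2) | (
        table["max_unique_peptides_single_rep"] >= 2
    )
    return ProteinCatalog(table)


def group_shared_peptides(
    incidence: Mapping[str, Sequence[str]], catalog: ProteinCatalog
) -> pd.DataFrame:
    """Group indistinguishable proteins by parsimony.

    Proteins with identical peptide sets are merged into one group whose
    representative is the lexicographically smallest id; a protein whose
    peptide set is a strict subset of another's is subsumed into that
    protein's group (flagged, not deleted). Proteins in the catalog with
    no peptide evidence form singleton groups.

    Parameters
    ----------
    incidence
        peptide_id -> iterable of protein ids carrying the peptide.
    catalog
        Catalog whose proteins are to be grouped; every protein named in
        ``incidence`` must appear in it.

    Returns
    -------
    DataFrame indexed by protein_id with columns ``group_id`` (the
    representative protein id) and ``subsumed`` (bool).
    """
    known = set(catalog.table.index)
    pepsets: dict[str, set[str]] = {p: set() for p in known}
    for pep, prots in incidence.items():
        prots = list(prots)
        if not prots:
            raise ValueError(f"peptide {pep!r} maps to no protein")
        for p in prots:
            if p not in known:
                raise ValueError(f"protein {p!r} in incidence but not in catalog")
            pepsets[p].add(pep)

    group_id: dict[str, str] = {}
    subsumed: dict[str, bool] = {}

    # proteins without peptide evidence stay singletons
    for p in known:
        if not pepsets[p]:
            group_id[p], subsumed[p] = p, False

    # identical-set merge: key groups by frozen peptide set
    by_set: dict[frozenset, list[str]] = {}
    for p in sorted(pepsets):
        if pepsets[p]:
            by_set.setdefault(frozenset(pepsets[p]), []).append(p)
    reps = {s: min(members) for s, members in by_set.items()}

    for s, members in by_set.items():
        # strict-subset subsumption into the largest strict superset
        # (ties broken by lexicographically smallest representative)
        supersets = [t for t in by_set if s < t]
        if supersets:
            target = min(supersets, key=lambda t: (-len(t), reps[t]))
            rep, sub = reps[target], True
        else:
            rep, sub = reps[s], False
        for p in members:
            group_id[p] = rep
            subsumed[p] = sub
    out = pd.DataFrame(
        {"group_id": pd.Series(group_id), "subsumed": pd.Series(subsumed)}
    ).sort_index()
    out.index.name = "protein_id"
    return out


def summarize_overlap(catalog: ProteinCatalog) -> dict:
    """Replicate-overlap summary of the included proteome.

    Returns counts of included proteins seen in >= 3 replicates, exactly 2,
    and in a single replicate with >= 2 unique peptides, plus the percent
    identified in all three replicates (``pct_all_reps``, one decimal;
    ``None`` for an empty catalog).
    """
    t = catalog.table[catalog.table["included"]]
    n_total = int(len(t))
    n3 = int((t["replicates_detected"] >= 3).sum())
    n2 = int((t["replicates_detected"] == 2).sum())
    n1m = int(
        (
            (t["replicates_detected"] == 1)
            & (t["max_unique_peptides_single_rep"] >= 2)
        ).sum()
    )
    pct = round(100.0 * n3 / n_total, 1) if n_total else None
    return {
        "n_in_3_reps": n3,
        "n_in_2_reps": n2,
        "n_single_rep_multi_peptide": n1m,
        "n_total_included": n_total,
        "pct_all_reps": pct,
    }


def write_catalog(catalog: ProteinCatalog, groups: pd.DataFrame | None, path) -> None:
    """Write the catalog (optionally with parsimony-group columns) as TSV."""
    t = catalog.table.copy()
    if groups is not None:
        t = t.join(groups)
    t.to_csv(path, sep="\t")


def load_peptide_incidence(path, delimiter: str = "\t") -> dict[str, list[str]]:
    """Read a peptide incidence table (peptide_id, comma-joined protein ids)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "peptide_id" not in df.columns or "protein_ids" not in df.columns:
        raise EvidenceFormatError("incidence table needs columns peptide_id, protein_ids")
    if df["peptide_id"].duplicated().any():
        raise ValueError("duplicate peptide_id in incidence table")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        prots = [p for p in str(row.protein_ids).split(",") if p]
        if not prots:
            raise ValueError(f"peptide {row.peptide_id!r} maps to no protein")
        out[str(row.peptide_id)] = prots
    return out
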