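"""Phylostratigraphic classification of proteins from homology hits.

Each protein of a focal species is assigned the widest clade (stratum) in
which homologs are detectable, using per-species BLAST-style hit evidence
thresholded at e-value < e_max and query coverage >= cov_min. The strata
form a strictly nested series (e.g. butterflies < Lepidoptera <
Mecopterida < Mecopterida+Tribolium < Insecta). A protein is:

* ``focal_specific``  — no hit in any non-focal species;
* ``conserved_all``   — a hit in every surveyed non-focal species;
* a stratum label     — hits confined to that stratum, phylogenetically
  continuous (every intermediate ring between the innermost and outermost
  hit carries at least one hit) and satisfying the stratum's evidence
  rule (e.g. Lepidoptera requires a non-focal butterfly and a moth);
* ``unresolved``      — any discontinuous or rule-failing pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

FOCAL_SPECIFIC = "focal_specific"
CONSERVED_ALL = "conserved_all"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class HitRecord:
    """One homology search hit (single HSP) for a query protein."""

    query_protein: str
    subject_species: str
    e_value: float
    query_coverage: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"query_coverage {self.query_coverage} outside [0, 1]")


@dataclass(frozen=True)
class EvidenceRequirement:
    """Minimum representation demanded within a species set."""

    label: str
    species: frozenset
    min_count: int = 1

    def satisfied(self, hit_species: frozenset) -> bool:
        return len(hit_species & self.species) >= self.min_count


@dataclass(frozen=True)
class TaxonSchema:
    """Strictly nested taxon strata around a focal species.

    ``strata`` runs from innermost to outermost; each stratum's species set
    must strictly contain all inner strata and include the focal species.
    ``evidence_rules`` maps a stratum label to the requirements a protein
    restricted to that stratum must meet (defaults: at least one hit in the
    stratum's own ring, which continuity already guarantees).
    """

    focal_species: str
    strata: tuple  # of (label, frozenset of species)
    evidence_rules: Mapping[str, tuple] = None  # label -> tuple[EvidenceRequirement]

    def __post_init__(self) -> None:
        prev = None
        for label, spp in self.strata:
            spp = frozenset(spp)
            if self.focal_species not in spp:
                raise ValueError(f"focal species missing from stratum {label!r}")
            if prev is not None and not prev < spp:
                raise ValueError(f"stratum {label!r} does not strictly contain its inner stratum")
            prev = spp
        if self.evidence_rules is None:
            object.__setattr__(self, "evidence_rules", {})

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.strata]

    @property
    def surveyed_species(self) -> frozenset:
        """All non-focal species covered by the outermost stratum."""
        return frozenset(self.strata[-1][1]) - {self.focal_species}

    def ring(self, i: int) -> frozenset:
        """Non-focal species of stratum i not in stratum i-1."""
        outer = frozenset(self.strata[i][1]) - {self.focal_species}
        if i == 0:
            return outer
        return outer - frozenset(self.strata[i - 1][1])

    def rules_for(self, label: str) -> tuple:
        return tuple(self.evidence_rules.get(label, ()))


def paper_schema() -> TaxonSchema:
    """The five-ring insect schema used for the Monarch sperm proteome.

    Focal species D. plexippus; strata: butterflies, Lepidoptera,
    Mecopterida, Mecopterida+Tribolium, Insecta (12 species total). The
    Lepidoptera stratum requires at least one non-focal butterfly and at
    least one moth.
    """
    focal = "D_plexippus"
    butterflies = frozenset({focal, "H_melpomene", "P_xuthus", "L_accius"})
    lepidoptera = butterflies | {"M_sexta", "A_transitella", "P_xylostella"}
    mecopterida = lepidoptera | {"D_melanogaster"}
    mecopterida_tribolium = mecopterida | {"T_castaneum"}
    insecta = mecopterida_tribolium | {"A_mellifera", "P_humanus", "A_pisum", "Z_nevadensis"}
    moths = lepidoptera - butterflies
    rules = {
        "lepidoptera": (
            EvidenceRequirement("non-focal butterfly", butterflies - {focal}),
            EvidenceRequirement("moth", moths),
        ),
    }
    return TaxonSchema(
        focal_species=focal,
        strata=(
            ("butterflies", butterflies),
            ("lepidoptera", lepidoptera),
            ("mecopterida", mecopterida),
            ("mecopterida_tribolium", mecopterida_tribolium),
            ("insecta", insecta),
        ),
        evidence_rules=rules,
    )


def build_hit_table(
    records: Iterable[HitRecord],
    e_max: float = 1e-5,
    cov_min: float = 0.5,
    proteins: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean protein x species hit table from thresholded hit records.

    hit(protein, species) is true iff some record for the pair has
    e_value < e_max (strict) and query_coverage >= cov_min. ``proteins``
    and ``species`` extend the table with all-False rows/columns for
    entities that received no passing record (needed so zero-hit proteins
    are still classified).
    """
    passing: dict[tuple[str, str], bool] = {}
    prot_ids = list(proteins) if proteins is not None else []
    sp_ids = list(species) if species is not None else []
    seen_p: set[str] = set(prot_ids)
    seen_s: set[str] = set(sp_ids)
    for rec in records:
        if rec.query_protein not in seen_p:
            seen_p.add(rec.query_protein)
            prot_ids.append(rec.query_protein)
        if rec.subject_species not in seen_s:
            seen_s.add(rec.subject_species)
            sp_ids.append(rec.subject_species)
        if rec.e_value < e_max and rec.query_coverage >= cov_min:
            passing[(rec.query_protein, rec.subject_species)] = True
    table = pd.DataFrame(False, index=sorted(prot_ids), columns=sorted(sp_ids))
    for (p, s) in passing:
        table.at[p, s] = True
    table.index.name = "protein_id"
    return table


def classify_hit_set(hit_species, schema: TaxonSchema) -> str:
    """Category for one protein given the species where homology was found."""
    hits = frozenset(hit_species) - {schema.focal_species}
    surveyed = schema.surveyed_species
    unknown = hits - surveyed
    if unknown:
        raise ValueError(f"hit species not covered by schema: {sorted(unknown)}")
    if not hits:
        return FOCAL_SPECIFIC
    if hits >= surveyed:
        return CONSERVED_ALL

    # innermost stratum containing all hits; continuity is anchored at the
    # focal species (the query protein exists there by definition), so every
    # ring from the innermost stratum out to the restriction stratum must
    # carry a hit — a hit pattern skipping intermediate clades is unresolved
    w = next(i for i, (_, spp) in enumerate(schema.strata) if hits <= frozenset(spp))
    continuous = all(hits & schema.ring(k) for k in range(w + 1))
    label = schema.strata[w][0]
    rules_ok = all(req.satisfied(hits) for req in schema.rules_for(label))
    return label if continuous and rules_ok else UNRESOLVED


def classify(protein_id: str, hits: pd.DataFrame, schema: TaxonSchema) -> str:
    """Category for one protein from a boolean hit table row."""
    row = hits.loc[protein_id]
    return classify_hit_set(frozenset(row.index[row]), schema)


def classify_all(hits: pd.DataFrame, schema: TaxonSchema) -> pd.Series:
    """Classify every protein in the hit table; returns a Series of categories."""
    out = {p: classify_hit_set(frozenset(hits.columns[hits.loc[p]]), schema) for p in hits.index}
    s = pd.Series(out, name="category")
    s.index.name = "protein_id"
    return s


def summarize(calls: pd.Series) -> pd.DataFrame:
    """Category counts, exact fractions and 1-decimal percentages.

    Percentages use round-half-even; the raw fraction column is included
    because 1-decimal rounding is lossy for reporting.
    """
    counts = calls.value_counts()
    n = int(counts.sum())
    frac = counts / n
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "fraction": frac,
            "pct": (100.0 * frac).round(1),
        }
    )


# ---------------------------------------------------------------------------
# input plumbing: BLAST tabular (outfmt 6) + subject->species map + query lengths

def load_blast_hits(
    path,
    species_map: Mapping[str, str],
    query_lengths: Mapping[str, int],
    delimiter: str = "\t",
) -> list[HitRecord]:
    """Parse BLAST outfmt-6-style rows into HitRecords.

    Expects at least the standard 12 columns (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore). Query
    coverage is the HSP's span on the query divided by query length; HSPs
    are not stitched. ``species_map`` maps subject sequence ids to species.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 12:
                raise ValueError(f"row {i}: expected >= 12 tab-separated fields, got {len(parts)}")
            qseqid, sseqid = parts[0], parts[1]
            try:
                qstart, qend = int(parts[6]), int(parts[7])
                evalue = float(parts[10])
            except ValueError as exc:
                raise ValueError(f"row {i}: malformed numeric field ({exc})") from exc
            if sseqid not in species_map:
                raise KeyError(f"row {i}: subject {sseqid!r} missing from species map")
            if qseqid not in query_lengths:
                raise KeyError(f"row {i}: query {qseqid!r} missing from length table")
            span = abs(qend - qstart) + 1
            cov = min(1.0, span / float(query_lengths[qseqid]))
            records.append(HitRecord(qseqid, species_map[sseqid], evalue, cov))
    return records


def load_schema(path, delimiter: str = "\t") -> TaxonSchema:
    """Read a schema file: first line ``focal<TAB>species``, then one line
    per stratum from innermost to outermost: ``label<TAB>sp1,sp2,...``
    (each stratum lists its full species set, focal included). An optional
    rule line ``rule<TAB>stratum_label<TAB>sp1,sp2,...`` adds a >=1
    requirement within the listed species."""
    focal = None
    strata: list[tuple[str, frozenset]] = []
    rules: dict[str, list[EvidenceRequirement]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if parts[0] == "focal":
                focal = parts[1]
            elif parts[0] == "rule":
                label, spp = parts[1], frozenset(parts[2].split(","))
                rules.setdefault(label, []).append(EvidenceRequirement(f"rule:{label}", spp))
            else:
                strata.append((parts[0], frozenset(parts[1].split(","))))
    if focal is None or not strata:
        raise ValueError("schema file needs a focal line and at least one stratum")
    return TaxonSchema(focal, tuple(strata), {k: tuple(v) for k, v in rules.items()})


def write_schema(schema: TaxonSchema, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"focal{delimiter}{schema.focal_species}\n")
        for label, spp in schema.strata:
            fh.write(f"{label}{delimiter}{','.join(sorted(spp))}\n")
        for label, reqs in schema.evidence_rules.items():
            for req in reqs:
                fh.write(f"rule{delimiter}{label}{delimiter}{','.join(sorted(req.species))}\n")
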