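"""Synthetic input bundles with planted, configurable effects.

Generates every table the pipeline consumes — replicate identification
evidence, peptide incidence, spectral counts with detection
probabilities, a cross-species abundance table with ortholog pairs,
differential-abundance calls, a gene x species ortholog matrix, homology
hit records against a nested taxon schema, and a per-gene divergence
table — together with the ground truth that was planted, so every
analysis stage can be tested for parameter recovery without external
data.

One master seed spawns named substreams (design, evidence, abundance,
orthology, hits, divergence, differential), so changing the parameters of
one block does not perturb the draws of the others. Identical
configuration and seed give a bitwise-identical bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abundance import DifferentialCall
from .orthology import OrthologyMatrix
from .phylostrat import (
    CONSERVED_ALL,
    FOCAL_SPECIFIC,
    UNRESOLVED,
    HitRecord,
    TaxonSchema,
    paper_schema,
    write_schema,
)

_STREAMS = ("design", "evidence", "abundance", "orthology", "hits", "divergence", "differential")

#: species surveyed for orthology (five insect orders)
ORTHOLOG_SPECIES = (
    "H_melpomene", "M_sexta", "P_xylostella", "B_mori",        # Lepidoptera
    "D_melanogaster", "A_gambiae",                              # Diptera
    "A_mellifera", "N_vitripennis",                             # Hymenoptera
    "T_castaneum", "D_ponderosae",                              # Coleoptera
    "A_pisum", "C_lectularius",                                 # Hemiptera
)
_LEPIDOPTERA_ORTHO = {"H_melpomene", "M_sexta", "P_xylostella", "B_mori"}


def _default_background_rates() -> dict:
    return {sp: (0.70 if sp in _LEPIDOPTERA_ORTHO else 0.60) for sp in ORTHOLOG_SPECIES}


def _default_sperm_rates() -> dict:
    # no deficit within Lepidoptera, a planted deficit outside it
    return {sp: (0.70 if sp in _LEPIDOPTERA_ORTHO else 0.45) for sp in ORTHOLOG_SPECIES}


def _default_mixture() -> dict:
    # category weights mirroring the magnitudes of a 584-protein proteome:
    # 45 focal-specific / 140 Lepidoptera-restricted / 173 conserved in all
    # surveyed species / 171 unresolved / 55 across the remaining strata
    return {
        FOCAL_SPECIFIC: 45 / 584,
        "butterflies": 25 / 584,
        "lepidoptera": 140 / 584,
        "mecopterida": 15 / 584,
        "mecopterida_tribolium": 15 / 584,
        CONSERVED_ALL: 173 / 584,
        UNRESOLVED: 171 / 584,
    }


def _default_dn_params() -> dict:
    # lognormal (mu, sigma) of dN per group: Lepidoptera-specific sperm
    # proteins evolve fastest, conserved sperm proteins slowest
    return {
        "lep_specific_sperm": (-2.35, 0.90),
        "conserved_sperm": (-3.35, 0.80),
        "genome_background": (-3.00, 0.80),
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the real study's magnitudes."""

    seed: int = 0
    n_genes: int = 15000
    n_sperm: int = 584
    n_decoy_low_confidence: int = 100
    n_replicates: int = 3

    # orthology block
    ortholog_rate_background: dict = field(default_factory=_default_background_rates)
    ortholog_rate_sperm: dict = field(default_factory=_default_sperm_rates)
    resample_iters: int = 5000

    # phylostratigraphy block
    stratum_mixture: dict = field(default_factory=_default_mixture)
    discontinuity_rate: float = 0.05
    hit_within_ring_rate: float = 0.6
    decoy_hit_rate: float = 0.10

    # divergence block
    dN_params: dict = field(default_factory=_default_dn_params)
    dS_params: tuple = (1.7, 0.5)
    dS_saturated: bool = True

    # abundance / MS block
    abundance_corr: float = 0.65
    abundance_log_sd: float = 1.5
    ms_depth: int = 37000
    detection_prob_beta: tuple = (6.0, 2.0)
    detect_intercept: float = 2.2
    detect_slope: float = 1.3
    peptides_mean: float = 6.9
    peptides_abundance_slope: float = 0.4
    shared_peptide_pairs: int = 12
    subset_peptide_pairs: int = 12

    # cross-species block
    ortho_pair_rate: float = 0.69
    one_to_one_rate: float = 0.91
    differential_fraction: float = 0.07
    differential_alpha: float = 0.05

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_sperm > self.n_genes:
            problems.append("n_sperm exceeds n_genes")
        for name in ("discontinuity_rate", "hit_within_ring_rate", "decoy_hit_rate",
                     "ortho_pair_rate", "one_to_one_rate", "differential_fraction",
                     "differential_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.abundance_corr <= 1.0:
            problems.append(f"abundance_corr={self.abundance_corr} outside [-1, 1]")
        if abs(sum(self.stratum_mixture.values()) - 1.0) > 1e-9:
            problems.append("stratum_mixture weights do not sum to 1")
        for d in (self.ortholog_rate_background, self.ortholog_rate_sperm):
            for sp, r in d.items():
                if not 0.0 <= r <= 1.0:
                    problems.append(f"ortholog rate for {sp}={r} outside [0, 1]")
        if min(self.n_genes, self.n_sperm, self.n_replicates, self.ms_depth) < 1:
            problems.append("sizes must be positive")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["dS_params"] = list(self.dS_params)
        d["detection_prob_beta"] = list(self.detection_prob_beta)
        d["dN_params"] = {k: list(v) for k, v in self.dN_params.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dS_params" in d:
            d["dS_params"] = tuple(d["dS_params"])
        if "detection_prob_beta" in d:
            d["detection_prob_beta"] = tuple(d["detection_prob_beta"])
        if "dN_params" in d:
            d["dN_params"] = {k: tuple(v) for k, v in d["dN_params"].items()}
        return cls(**d)


def scenario_paper_like() -> SimulationConfig:
    """The default demonstration configuration (study-sized magnitudes)."""
    cfg = SimulationConfig()
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """What was planted, aligned with the emitted tables."""

    sperm_ids: list
    planted_category: pd.Series        # sperm protein -> stratum category
    group: pd.Series                   # gene -> divergence group (or 'excluded')
    detection: pd.DataFrame            # sperm protein x replicate bool
    log_abundance_a: pd.Series         # focal species, log scale
    log_abundance_b: pd.Series         # second species, log scale
    differential_direction: pd.Series  # +1 / -1 planted sign, 0 = null


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    schema: TaxonSchema
    evidence: pd.DataFrame
    peptide_incidence: dict
    counts_a: pd.Series
    probs_a: pd.Series
    abundance_b: pd.Series
    ortholog_pairs: pd.DataFrame
    differential_calls: list
    ortholog_matrix: OrthologyMatrix
    hit_records: list
    divergence: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        """Emit the bundle as plain TSV/YAML files under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "peptide_id": list(self.peptide_incidence),
                "protein_ids": [",".join(sorted(v)) for v in self.peptide_incidence.values()],
            }
        ).to_csv(out / "peptides.tsv", sep="\t", index=False)
        self.counts_a.rename("count").rename_axis("protein_id").to_csv(out / "counts_a.tsv", sep="\t")
        self.probs_a.rename("detection_prob").rename_axis("protein_id").to_csv(out / "probs_a.tsv", sep="\t")
        self.abundance_b.rename("abundance").rename_axis("protein_id").to_csv(out / "abundance_b.tsv", sep="\t")
        self.ortholog_pairs.to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "protein_id": [c.protein_id for c in self.differential_calls],
                "log_fold_change": [c.log_fold_change for c in self.differential_calls],
                "adjusted_p": [c.adjusted_p for c in self.differential_calls],
            }
        ).to_csv(out / "differential_calls.tsv", sep="\t", index=False)
        mat = self.ortholog_matrix.presence.copy()
        mat.insert(0, "in_focal", self.ortholog_matrix.in_focal)
        mat.rename_axis("gene_id").to_csv(out / "ortholog_matrix.tsv", sep="\t")
        pd.DataFrame(
            {
                "query_protein": [r.query_protein for r in self.hit_records],
                "subject_species": [r.subject_species for r in self.hit_records],
                "e_value": [r.e_value for r in self.hit_records],
                "query_coverage": [r.query_coverage for r in self.hit_records],
            }
        ).to_csv(out / "hits.tsv", sep="\t", index=False)
        self.divergence.rename_axis("gene_id").to_csv(out / "divergence.tsv", sep="\t")
        self.truth.planted_category.rename("category").rename_axis("protein_id").to_csv(
            out / "truth_categories.tsv", sep="\t"
        )
        write_schema(self.schema, out / "schema.tsv")
        self.config.to_yaml(out / "config.yaml")


def load_hit_records(path, delimiter: str = "\t") -> list[HitRecord]:
    """Read back a simple hit-record table (as written by the bundle)."""
    df = pd.read_csv(path, sep=delimiter, dtype={"query_protein": str, "subject_species": str},
                     float_precision="round_trip")
    return [
        HitRecord(str(r.query_protein), str(r.subject_species), float(r.e_value), float(r.query_coverage))
        for r in df.itertuples(index=False)
    ]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _plant_hit_set(category: str, schema: TaxonSchema, rng: np.random.Generator) -> frozenset:
    """A hit species set that classifies exactly as the planted category."""
    surveyed = sorted(schema.surveyed_species)
    rings = [sorted(schema.ring(i)) for i in range(len(schema.strata))]
    if category == FOCAL_SPECIFIC:
        return frozenset()
    if category == CONSERVED_ALL:
        return frozenset(surveyed)
    if category == UNRESOLVED:
        # two guaranteed-discontinuous templates: skip the moth ring, or
        # hit moths only (fails the butterfly requirement of Lepidoptera)
        if rng.random() < 0.5:
            return frozenset({rng.choice(rings[0]), rng.choice(rings[2])})
        k = rng.integers(1, len(rings[1]) + 1)
        return frozenset(rng.choice(rings[1], size=k, replace=False))
    w = schema.labels.index(category)
    hits: set = set()
    for i in range(w + 1):
        ring = rings[i]
        chosen = [sp for sp in ring if rng.random() < 0.6]
        if not chosen:
            chosen = [rng.choice(ring)]
        hits.update(chosen)
    if w == len(schema.strata) - 1 and frozenset(hits) >= frozenset(surveyed):
        # outermost-stratum category must not cover every surveyed species
        hits.discard(rings[w][-1])
    return frozenset(hits)


def _corrupt_hit_set(hits: frozenset, schema: TaxonSchema, rng: np.random.Generator) -> frozenset:
    """Make a continuous pattern discontinuous (used by discontinuity_rate)."""
    rings = [sorted(schema.ring(i)) for i in range(len(schema.strata))]
    non_focal = set(hits)
    occupied = [i for i in range(len(rings)) if non_focal & set(rings[i])]
    w = max(occupied) if occupied else -1
    if w + 2 < len(rings):
        return frozenset(non_focal | {rng.choice(rings[w + 2])})
    # already in the outermost rings: remove an intermediate ring instead
    if len(occupied) >= 3:
        mid = occupied[len(occupied) // 2]
        return frozenset(non_focal - set(rings[mid]))
    return frozenset(non_focal)


def generate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedBundle:
    """Generate a full synthetic bundle with planted effects.

    ``seed`` overrides ``config.seed`` when given. All tables are mutually
    consistent with the returned :class:`GroundTruth`.
    """
    cfg = dataclasses.replace(config) if config is not None else scenario_paper_like()
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    schema = paper_schema()
    rng = {
        name: np.random.default_rng(ss)
        for name, ss in zip(_STREAMS, np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS)))
    }

    # --- design: gene universe and sperm membership -----------------------
    gene_ids = np.array([f"G{i:06d}" for i in range(cfg.n_genes)])
    sperm_idx = np.sort(rng["design"].choice(cfg.n_genes, size=cfg.n_sperm, replace=False))
    sperm_ids = [str(g) for g in gene_ids[sperm_idx]]
    sperm_set = set(sperm_ids)

    cats = list(cfg.stratum_mixture)
    weights = np.array([cfg.stratum_mixture[c] for c in cats], dtype=float)
    planted = rng["design"].choice(len(cats), size=cfg.n_sperm, p=weights / weights.sum())
    planted_category = pd.Series([cats[i] for i in planted], index=sperm_ids, name="category")

    # --- abundance: correlated lognormal pair + MS observation ------------
    rho, s = cfg.abundance_corr, cfg.abundance_log_sd
    cov = np.array([[1.0, rho], [rho, 1.0]]) * s**2
    z = rng["abundance"].multivariate_normal([0.0, 0.0], cov, size=cfg.n_sperm)
    log_a = pd.Series(z[:, 0], index=sperm_ids, name="log_abundance_a")
    log_b_all = pd.Series(z[:, 1], index=sperm_ids, name="log_abundance_b")
    share_a = np.exp(log_a.to_numpy())
    share_a = share_a / share_a.sum()

    a_beta, b_beta = cfg.detection_prob_beta
    probs_a = pd.Series(
        np.clip(rng["abundance"].beta(a_beta, b_beta, size=cfg.n_sperm), 0.05, 1.0),
        index=sperm_ids,
        name="detection_prob",
    )
    # observed spectra scale with true abundance AND detectability; the
    # APEX correction n_i / O_i then recovers the abundance share
    lam = cfg.ms_depth * share_a * probs_a.to_numpy()
    lam = lam / lam.sum() * cfg.ms_depth

    # --- evidence: merged spectra split across replicates ------------------
    # the merged-experiment spectral count carries only Poisson noise around
    # abundance x detectability; replicate identification requires spectra
    # in that replicate AND a logistic search-success draw in log abundance
    zs = (log_a.to_numpy() - log_a.mean()) / max(log_a.std(ddof=0), 1e-12)
    p_detect = _sigmoid(cfg.detect_intercept + cfg.detect_slope * zs)
    merged = rng["evidence"].poisson(lam)
    rep_counts = np.stack(
        [rng["evidence"].multinomial(m, np.full(cfg.n_replicates, 1.0 / cfg.n_replicates))
         for m in merged]
    )
    detection = (rep_counts > 0) & (
        rng["evidence"].random((cfg.n_sperm, cfg.n_replicates)) < p_detect[:, None]
    )
    rep_ids = [f"R{r + 1}" for r in range(cfg.n_replicates)]
    det_df = pd.DataFrame(detection, index=sperm_ids, columns=rep_ids)

    up_mu = cfg.peptides_mean * np.exp(cfg.peptides_abundance_slope * zs)
    ev_rows = []
    for j, rep in enumerate(rep_ids):
        det = detection[:, j]
        up = 1 + rng["evidence"].poisson(up_mu)
        prob = 0.99 + 0.01 * rng["evidence"].beta(2.0, 1.0, size=cfg.n_sperm)
        for i in np.flatnonzero(det):
            ev_rows.append((sperm_ids[i], rep, int(up[i]), int(rep_counts[i, j]), float(prob[i])))
    counts_total = np.where(detection.any(axis=1), merged, 0).astype(float)
    # decoy identifications that the confidence / inclusion filters reject
    for d in range(cfg.n_decoy_low_confidence):
        pid = f"DECOY{d:04d}"
        rep = rep_ids[int(rng["evidence"].integers(cfg.n_replicates))]
        if rng["evidence"].random() < 0.5:
            ev_rows.append((pid, rep, 1, int(1 + rng["evidence"].poisson(1.0)), 1.0))
        else:
            ev_rows.append((pid, rep, int(2 + rng["evidence"].poisson(2.0)),
                            int(3 + rng["evidence"].poisson(3.0)),
                            float(rng["evidence"].uniform(0.5, 0.99))))
    evidence = pd.DataFrame(
        ev_rows,
        columns=["protein_id", "replicate_id", "unique_peptides", "spectral_count", "protein_prob"],
    )
    counts_a = pd.Series(counts_total, index=sperm_ids, name="count")

    # --- peptide incidence: unique peptides plus planted shared structure -
    n_pep = np.maximum(1, rng["evidence"].poisson(up_mu))
    pepsets = {pid: {f"PEP_{pid}_{k}" for k in range(n_pep[i])} for i, pid in enumerate(sperm_ids)}
    order = rng["evidence"].permutation(cfg.n_sperm)
    dup_pairs = order[: 2 * cfg.shared_peptide_pairs].reshape(-1, 2)
    sub_pairs = order[2 * cfg.shared_peptide_pairs: 2 * (cfg.shared_peptide_pairs + cfg.subset_peptide_pairs)].reshape(-1, 2)
    for i, j in dup_pairs:
        pepsets[sperm_ids[j]] = set(pepsets[sperm_ids[i]])
    for i, j in sub_pairs:
        donor = pepsets[sperm_ids[i]]
        if len(donor) >= 2:
            k = int(rng["evidence"].integers(1, len(donor)))
            pepsets[sperm_ids[j]] = set(sorted(donor)[:k])
    incidence: dict[str, list[str]] = {}
    for pid, peps in pepsets.items():
        for pep in peps:
            incidence.setdefault(pep, []).append(pid)
    incidence = {k: sorted(v) for k, v in sorted(incidence.items())}

    # --- cross-species pairs, second-species profile, differential calls --
    paired = rng["differential"].random(cfg.n_sperm) < cfg.ortho_pair_rate
    pair_ids = [pid for pid, f in zip(sperm_ids, paired) if f]
    b_ids = {pid: f"B_{pid}" for pid in pair_ids}
    one2one = rng["differential"].random(len(pair_ids)) < cfg.one_to_one_rate
    ortholog_pairs = pd.DataFrame(
        {"id_a": pair_ids, "id_b": [b_ids[p] for p in pair_ids], "one_to_one": one2one}
    )
    share_b = np.exp(log_b_all.loc[pair_ids].to_numpy())
    abundance_b = pd.Series(share_b / share_b.sum(), index=[b_ids[p] for p in pair_ids], name="abundance")

    n_pairs = len(pair_ids)
    n_sig = int(round(cfg.differential_fraction * n_pairs))
    sig_idx = rng["differential"].choice(n_pairs, size=n_sig, replace=False)
    direction = pd.Series(0, index=pair_ids, dtype=int, name="differential_direction")
    calls: list[DifferentialCall] = []
    sig_set = set(sig_idx.tolist())
    for i, pid in enumerate(pair_ids):
        if i in sig_set:
            d = 1 if rng["differential"].random() < 0.5 else -1
            direction.iloc[i] = d
            lfc = d * (0.5 + rng["differential"].exponential(1.0))
            p_adj = float(rng["differential"].uniform(0.0, 0.9 * cfg.differential_alpha))
        else:
            lfc = float(rng["differential"].normal(0.0, 0.3))
            p_adj = float(rng["differential"].uniform(cfg.differential_alpha, 1.0))
        calls.append(DifferentialCall(pid, float(lfc), p_adj))

    # --- ortholog matrix ---------------------------------------------------
    in_focal = pd.Series([g in sperm_set for g in gene_ids], index=gene_ids, name="in_focal")
    presence = {}
    for sp in ORTHOLOG_SPECIES:
        r_bg = cfg.ortholog_rate_background[sp]
        r_sp = cfg.ortholog_rate_sperm[sp]
        rates = np.where(in_focal.to_numpy(), r_sp, r_bg)
        presence[sp] = rng["orthology"].random(cfg.n_genes) < rates
    presence = pd.DataFrame(presence, index=gene_ids)
    presence.index.name = "gene_id"
    ortholog_matrix = OrthologyMatrix(presence, in_focal)

    # --- homology hit records ---------------------------------------------
    surveyed = sorted(schema.surveyed_species)
    hit_records: list[HitRecord] = []
    truth_cats = planted_category.to_dict()
    for pid in sperm_ids:
        cat = truth_cats[pid]
        hits = _plant_hit_set(cat, schema, rng["hits"])
        if (
            cfg.discontinuity_rate > 0
            and cat not in (FOCAL_SPECIFIC, CONSERVED_ALL, UNRESOLVED)
            and rng["hits"].random() < cfg.discontinuity_rate
        ):
            hits = _corrupt_hit_set(hits, schema, rng["hits"])
        for sp in sorted(hits):
            e = 10.0 ** rng["hits"].uniform(-150.0, -6.0)
            cov = rng["hits"].uniform(0.5, 1.0)
            hit_records.append(HitRecord(pid, sp, float(e), float(cov)))
            if rng["hits"].random() < 0.3:  # an extra failing HSP; OR semantics must hold
                hit_records.append(
                    HitRecord(pid, sp, float(10.0 ** rng["hits"].uniform(-4.9, 1.0)),
                              float(rng["hits"].uniform(0.0, 1.0)))
                )
        for sp in surveyed:
            if sp not in hits and rng["hits"].random() < cfg.decoy_hit_rate:
                if rng["hits"].random() < 0.5:
                    rec = HitRecord(pid, sp, float(10.0 ** rng["hits"].uniform(-4.9, 1.0)),
                                    float(rng["hits"].uniform(0.0, 1.0)))
                else:
                    rec = HitRecord(pid, sp, float(10.0 ** rng["hits"].uniform(-150.0, -6.0)),
                                    float(rng["hits"].uniform(0.0, 0.4999)))
                hit_records.append(rec)

    # --- divergence table ---------------------------------------------------
    lep_cats = {"butterflies", "lepidoptera"}
    cons_cats = {"mecopterida", "mecopterida_tribolium", "insecta", CONSERVED_ALL}
    group = {}
    for g in gene_ids:
        g = str(g)
        if g not in sperm_set:
            group[g] = "genome_background"
        else:
            cat = truth_cats[g]
            if cat in lep_cats:
                group[g] = "lep_specific_sperm"
            elif cat in cons_cats:
                group[g] = "conserved_sperm"
            else:
                group[g] = "excluded"  # focal-specific / unresolved: no ortholog alignment
    group = pd.Series(group, name="group")
    div_ids = group.index[group != "excluded"]
    mu = np.array([cfg.dN_params[group[g]][0] for g in div_ids])
    sg = np.array([cfg.dN_params[group[g]][1] for g in div_ids])
    dn = np.exp(rng["divergence"].normal(mu, sg))
    ds_mu, ds_sg = cfg.dS_params if cfg.dS_saturated else (-1.2, 0.5)
    ds = np.exp(rng["divergence"].normal(ds_mu, ds_sg, size=len(div_ids)))
    divergence = pd.DataFrame({"dN": dn, "dS": ds, "group": group.loc[div_ids]}, index=div_ids)
    divergence.index.name = "gene_id"

    truth = GroundTruth(
        sperm_ids=sperm_ids,
        planted_category=planted_category,
        group=group,
        detection=det_df,
        log_abundance_a=log_a,
        log_abundance_b=log_b_all,
        differential_direction=direction,
    )
    return SimulatedBundle(
        config=cfg,
        schema=schema,
        evidence=evidence,
        peptide_incidence=incidence,
        counts_a=counts_a,
        probs_a=probs_a,
        abundance_b=abundance_b,
        ortholog_pairs=ortholog_pairs,
        differential_calls=calls,
        ortholog_matrix=ortholog_matrix,
        hit_records=hit_records,
        divergence=divergence,
        truth=truth,
    )
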