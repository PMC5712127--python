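"""Replicate-evidence parsing, confidence and inclusion filters, parsimony grouping."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermevol import evidence as ev
from conftest import make_evidence


def write_tsv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadEvidence:
    def test_well_formed_table_parses_identity(self, tmp_path):
        p = write_tsv(
            tmp_path,
            "ev.tsv",
            "protein_id\treplicate_id\tunique_peptides\tspectral_count\tprotein_prob\n"
            "P1\tR1\t2\t5\t0.999\nP1\tR2\t1\t2\t0.995\nP2\tR1\t3\t9\t1.0\n",
        )
        records = ev.load_evidence(p)
        assert len(records) == 3
        assert records[0] == ev.ReplicateEvidence("P1", "R1", 2, 5, 0.999)

    def test_missing_column_is_format_error(self, tmp_path):
        p = write_tsv(
            tmp_path,
            "bad.tsv",
            "protein_id\tunique_peptides\tspectral_count\tprotein_prob\nP1\t2\t5\t0.999\n",
        )
        with pytest.raises(ev.EvidenceFormatError, match="replicate_id"):
            ev.load_evidence(p)

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("P1\tR1\t2\t5\t1.2", "protein_prob"),
            ("P1\tR1\t-1\t5\t0.9", "negative"),
            ("P1\tR1\t2\t-5\t0.9", "negative"),
        ],
    )
    def test_out_of_range_values_rejected(self, tmp_path, row, msg):
        p = write_tsv(
            tmp_path,
            "bad.tsv",
            "protein_id\treplicate_id\tunique_peptides\tspectral_count\tprotein_prob\n"
            + row + "\n",
        )
        with pytest.raises(ValueError, match=msg):
            ev.load_evidence(p)

    def test_duplicate_protein_replicate_pair_rejected(self, tmp_path):
        p = write_tsv(
            tmp_path,
            "dup.tsv",
            "protein_id\treplicate_id\tunique_peptides\tspectral_count\tprotein_prob\n"
            "P1\tR1\t2\t5\t0.999\nP1\tR1\t1\t2\t0.995\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            ev.load_evidence(p)


class TestConfidenceFilter:
    def test_strictly_greater_than_threshold(self):
        records = make_evidence(
            [("P1", "R1", 1, 1, 0.99), ("P2", "R1", 1, 1, 0.991), ("P3", "R1", 1, 1, 1.0)]
        )
        kept = ev.filter_confident(records, 0.99)
        assert [r.protein_id for r in kept] == ["P2", "P3"]

    def test_empty_input_gives_empty_output(self):
        assert ev.filter_confident([], 0.99) == []

    def test_zero_threshold_keeps_positive_probabilities(self):
        records = make_evidence([("P1", "R1", 1, 1, 0.0), ("P2", "R1", 1, 1, 0.01)])
        assert [r.protein_id for r in ev.filter_confident(records, 0.0)] == ["P2"]


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "rows,expected_included",
        [
            # two replicates, one peptide each -> in
            ([("P", "A", 1, 1, 1.0), ("P", "B", 1, 1, 1.0)], True),
            # one replicate, two unique peptides -> in
            ([("P", "A", 2, 2, 1.0)], True),
            # one replicate, one peptide -> out
            ([("P", "A", 1, 3, 1.0)], False),
        ],
    )
    def test_inclusion_criteria(self, rows, expected_included):
        catalog = ev.apply_inclusion_filter(make_evidence(rows))
        assert bool(catalog.table.loc["P", "included"]) is expected_included

    def test_multi_peptide_rule_is_per_replicate_not_pooled(self):
        # one unique peptide in each of... only one replicate at a time:
        # same protein seen once with 1 peptide is excluded even though
        # another protein pools 2 peptides across two replicates
        catalog = ev.apply_inclusion_filter(
            make_evidence([("P", "A", 1, 1, 1.0)])
        )
        assert not catalog.table.loc["P", "included"]

    def test_catalog_counts_match_evidence(self):
        rows = [
            ("P1", "A", 2, 5, 1.0),
            ("P1", "B", 1, 3, 1.0),
            ("P1", "C", 4, 7, 1.0),
            ("P2", "A", 1, 2, 1.0),
        ]
        t = ev.apply_inclusion_filter(make_evidence(rows)).table
        assert t.loc["P1", "replicates_detected"] == 3
        assert t.loc["P1", "max_unique_peptides_single_rep"] == 4
        assert t.loc["P1", "total_spectra"] == 15
        assert t.loc["P2", "replicates_detected"] == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["P1", "P2", "P3"]),
                st.sampled_from(["A", "B", "C"]),
                st.integers(0, 5),
                st.integers(0, 9),
            ),
            max_size=12,
        ),
        st.tuples(
            st.sampled_from(["P1", "P2", "P3"]),
            st.sampled_from(["A", "B", "C"]),
            st.integers(0, 5),
            st.integers(0, 9),
        ),
    )
    @settings(max_examples=60, deadline=None)
    def test_inclusion_is_monotone_in_evidence(self, rows, extra):
        """Adding an evidence row never flips a protein from included to
        excluded. Rows must keep (protein, replicate) unique, so the extra
        row only counts when that slot was empty."""
        def dedupe(rws):
            d = {}
            for p, r, u, s in rws:
                d.setdefault((p, r), (p, r, u, s))
            return [(*v, 1.0) for v in d.values()]

        before = ev.apply_inclusion_filter(make_evidence(dedupe(rows))).table
        after = ev.apply_inclusion_filter(make_evidence(dedupe(rows + [extra]))).table
        for pid in before.index[before["included"]]:
            assert bool(after.loc[pid, "included"])


def brute_force_min_cover(pepsets):
    """Smallest protein set covering all peptides (exhaustive search)."""
    universe = set().union(*pepsets.values())
    prots = sorted(pepsets)
    for size in range(len(prots) + 1):
        for combo in itertools.combinations(prots, size):
            if set().union(*(pepsets[p] for p in combo), set()) >= universe:
                return size
    return len(prots)


class TestParsimonyGrouping:
    def _catalog(self, ids):
        rows = [(p, "A", 2, 2, 1.0) for p in ids]
        return ev.apply_inclusion_filter(make_evidence(rows))

    def _group(self, pepsets):
        incidence = {}
        for p, peps in pepsets.items():
            for pep in peps:
                incidence.setdefault(pep, []).append(p)
        return ev.group_shared_peptides(incidence, self._catalog(pepsets))

    def test_identical_sets_merge_with_lexicographic_representative(self):
        g = self._group({"P2": {"a", "b"}, "P1": {"a", "b"}})
        assert g.loc["P1", "group_id"] == "P1"
        assert g.loc["P2", "group_id"] == "P1"
        assert not g["subsumed"].any()

    def test_strict_subset_is_subsumed(self):
        g = self._group({"P3": {"a"}, "P4": {"a", "b"}})
        assert g.loc["P3", "group_id"] == "P4"
        assert bool(g.loc["P3", "subsumed"])
        assert not g.loc["P4", "subsumed"]

    def test_disjoint_sets_stay_separate(self):
        g = self._group({"P1": {"a"}, "P2": {"b"}, "P3": {"c"}})
        assert g["group_id"].nunique() == 3
        assert not g["subsumed"].any()

    def test_partial_overlap_is_not_subsumed(self):
        # {a,b} and {b,c} share a peptide but neither subsumes the other
        g = self._group({"P1": {"a", "b"}, "P2": {"b", "c"}})
        assert g["group_id"].nunique() == 2
        assert not g["subsumed"].any()

    def test_grouping_is_order_independent(self):
        pepsets = {"P1": {"a", "b"}, "P2": {"a", "b"}, "P3": {"a"}, "P4": {"c"}}
        incidence = {}
        for p, peps in pepsets.items():
            for pep in peps:
                incidence.setdefault(pep, []).append(p)
        base = ev.group_shared_peptides(incidence, self._catalog(pepsets))
        for perm in itertools.permutations(incidence.items()):
            g = ev.group_shared_peptides(dict(perm), self._catalog(pepsets))
            pd.testing.assert_frame_equal(g, base)

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_group_count_matches_minimal_explanation_oracle(self, data):
        """On nested/duplicate/disjoint families the number of parsimony
        groups equals the exhaustive minimal-cover size."""
        n_base = data.draw(st.integers(1, 3))
        base = {f"B{i}": {f"pep{i}_{k}" for k in range(data.draw(st.integers(2, 3)))}
                for i in range(n_base)}
        pepsets = dict(base)
        for j in range(data.draw(st.integers(0, 3))):
            donor = data.draw(st.sampled_from(sorted(base)))
            if data.draw(st.booleans()):
                pepsets[f"D{j}"] = set(base[donor])  # duplicate
            else:
                k = data.draw(st.integers(1, len(base[donor]) - 1))
                pepsets[f"S{j}"] = set(sorted(base[donor])[:k])  # strict subset
        g = self._group(pepsets)
        n_groups = g.loc[~g["subsumed"], "group_id"].nunique()
        assert n_groups == brute_force_min_cover(pepsets)

    def test_protein_in_incidence_but_not_catalog_is_an_error(self):
        with pytest.raises(ValueError, match="not in catalog"):
            ev.group_shared_peptides({"a": ["P1", "PX"]}, self._catalog(["P1"]))


class TestOverlapSummary:
    def test_paper_scale_percent(self):
        # 240 proteins in all three replicates of a 584-protein proteome
        rows = []
        for i in range(240):
            rows += [(f"T{i:03d}", r, 1, 1, 1.0) for r in "ABC"]
        for i in range(140):
            rows += [(f"U{i:03d}", r, 1, 1, 1.0) for r in "AB"]
        for i in range(204):
            rows += [(f"V{i:03d}", "A", 2, 2, 1.0)]
        s = ev.summarize_overlap(ev.apply_inclusion_filter(make_evidence(rows)))
        assert s["n_total_included"] == 584
        assert s["n_in_3_reps"] == 240
        assert s["pct_all_reps"] == 41.1

    def test_single_protein_all_replicates_is_100_pct(self):
        rows = [("P", r, 1, 1, 1.0) for r in "ABC"]
        s = ev.summarize_overlap(ev.apply_inclusion_filter(make_evidence(rows)))
        assert s["pct_all_reps"] == 100.0

    def test_empty_catalog_reports_absent_percentage(self):
        s = ev.summarize_overlap(ev.apply_inclusion_filter([]))
        assert s["n_total_included"] == 0 and s["pct_all_reps"] is None

    def test_generator_detection_truth_recovered(self, small_bundle):
        """Replicate-detection counts in the catalog equal the planted
        detection matrix of the generator."""
        confident = ev.filter_confident(
            make_evidence(
                small_bundle.evidence.itertuples(index=False, name=None)
            )
        )
        catalog = ev.apply_inclusion_filter(confident)
        det = small_bundle.truth.detection
        for pid in catalog.table.index:
            if pid.startswith("DECOY"):
                continue
            assert catalog.table.loc[pid, "replicates_detected"] == det.loc[pid].sum()
        # every decoy identification fails the confidence or inclusion filter
        decoys = catalog.table.index.str.startswith("DECOY")
        assert not catalog.table.loc[decoys, "included"].any()
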