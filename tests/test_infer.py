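from itertools import combinations

import pandas as pd
import pytest

from hemoshotgun.classify import classify_psms
from hemoshotgun.infer import (
    InferenceError,
    identification_summary,
    infer_proteins,
    minimal_cover,
)

from conftest import make_db, psm_frame


def classified(db, rows):
    return classify_psms(psm_frame(rows), db)


def exhaustive_min_cover_size(cand_map):
    """Oracle: try every subset of candidates by increasing size."""
    cands = sorted(
        {c for cs in cand_map.values() for c in cs}, key=lambda c: tuple(sorted(c))
    )
    for k in range(1, len(cands) + 1):
        for combo in combinations(cands, k):
            if all(set(combo) & cs for cs in cand_map.values()):
                return k
    raise AssertionError("no cover exists")


class TestMinimalCover:
    def test_spec_worked_example(self):
        a, b, c = frozenset({"A"}), frozenset({"B"}), frozenset({"C"})
        cover, algo = minimal_cover({"p1": {a, b}, "p2": {b, c}})
        assert cover == [b]
        assert algo == "exact"

    def test_single_candidate(self):
        only = frozenset({"X"})
        cover, _ = minimal_cover({"p": {only}})
        assert cover == [only]

    def test_disjoint_candidates_lower_bound(self):
        cand_map = {
            f"p{i}": {frozenset({f"prot{i}"})} for i in range(5)
        }
        cover, _ = minimal_cover(cand_map)
        assert len(cover) == 5

    def test_empty_candidate_set_raises(self):
        with pytest.raises(InferenceError):
            minimal_cover({"p": set()})

    def test_deterministic_tie_break(self):
        a, b = frozenset({"A"}), frozenset({"B"})
        cover, _ = minimal_cover({"p": {a, b}})
        assert cover == [a]  # lexicographically smallest equal-size optimum

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n_prot = int(rng.integers(2, 10))
            prots = [frozenset({f"q{i}"}) for i in range(n_prot)]
            cand_map = {}
            for p in range(int(rng.integers(2, 8))):
                size = int(rng.integers(1, min(4, n_prot) + 1))
                idx = rng.choice(n_prot, size=size, replace=False)
                cand_map[f"pep{p}"] = {prots[i] for i in idx}
            cover, algo = minimal_cover(cand_map)
            assert algo == "exact"
            assert len(cover) == exhaustive_min_cover_size(cand_map)

    def test_greedy_beyond_limit(self, rng):
        prots = [frozenset({f"q{i:02d}"}) for i in range(30)]
        cand_map = {f"pep{i}": {prots[i], prots[(i + 1) % 30]} for i in range(30)}
        cover, algo = minimal_cover(cand_map, exact_limit=20)
        assert algo == "greedy"
        assert all(set(cover) & cs for cs in cand_map.values())


class TestInferProteins:
    def test_single_1a_peptide_two_psms(self, tiny_db):
        cls = classified(
            tiny_db,
            [("s1", "TTTVVV", 9.0, False, "fed"),
             ("s2", "TTTVVV", 9.0, False, "fed")],
        )
        groups = infer_proteins(cls, tiny_db, min_psms=2)
        assert len(groups) == 1
        assert groups[0].evidence_tier == "unambiguous"
        assert groups[0].member_protein_ids == {"pE1"}

    def test_min_psms_filters_single_psm(self, tiny_db):
        cls = classified(tiny_db, [("s1", "TTTVVV", 9.0, False, "fed")])
        assert infer_proteins(cls, tiny_db, min_psms=2) == []
        assert len(infer_proteins(cls, tiny_db, min_psms=1)) == 1

    def test_3a_lists_all_encoding_genes(self, tiny_db):
        cls = classified(
            tiny_db,
            [("s1", "HHHHLLL", 9.0, False, "fed"),
             ("s2", "HHHHLLL", 9.0, False, "fed")],
        )
        groups = infer_proteins(cls, tiny_db)
        assert len(groups) == 1
        assert groups[0].implied_gene_ids == {"gC", "gD"}
        assert groups[0].evidence_tier == "unambiguous"

    def test_gene_model_group_from_2b(self, tiny_db):
        cls = classified(
            tiny_db,
            [("s1", "WWNDFGHTTYE", 9.0, False, "fed"),
             ("s2", "WWNDFGHTTYE", 9.0, False, "fed")],
        )
        groups = infer_proteins(cls, tiny_db)
        assert len(groups) == 1
        assert groups[0].evidence_tier == "gene-model"
        assert groups[0].implied_gene_ids == {"gB"}

    def test_3b_absorbed_by_existing_identification(self):
        db = make_db(
            ("p1", "t1", "g1", "SHAREDWWAAACCCDDD"),
            ("p2", "t2", "g2", "SHAREDWWEEEFFFGGG"),
        )
        rows = [
            ("s1", "AAACCCDDD", 9.0, False, "fed"),
            ("s2", "AAACCCDDD", 9.0, False, "fed"),
            ("s3", "SHAREDWW", 9.0, False, "fed"),
            ("s4", "SHAREDWW", 9.0, False, "fed"),
        ]
        groups = infer_proteins(classified(db, rows), db)
        # 3b peptide SHAREDWW is contained in already-identified p1
        assert len(groups) == 1
        assert groups[0].member_protein_ids == {"p1"}
        assert "SHAREDWW" in groups[0].supporting_peptides
        assert groups[0].psm_count == 4

    def test_orphan_3b_goes_to_cover(self):
        db = make_db(
            ("p1", "t1", "g1", "SHAREDWWAAACCCDDD"),
            ("p2", "t2", "g2", "SHAREDWWEEEFFFGGG"),
        )
        rows = [
            ("s1", "SHAREDWW", 9.0, False, "fed"),
            ("s2", "SHAREDWW", 9.0, False, "fed"),
        ]
        groups = infer_proteins(classified(db, rows), db)
        assert len(groups) == 1
        assert groups[0].evidence_tier == "cover"
        # both proteins share the containment pattern -> one group of both
        assert groups[0].member_protein_ids == {"p1", "p2"}

    def test_parsimony_adding_1a_never_increases_groups(self):
        db = make_db(
            ("p1", "t1", "g1", "SHAREDWWAAACCCDDD"),
            ("p2", "t2", "g2", "SHAREDWWEEEFFFGGG"),
        )
        base_rows = [
            ("s1", "SHAREDWW", 9.0, False, "fed"),
            ("s2", "SHAREDWW", 9.0, False, "fed"),
        ]
        extra_rows = base_rows + [
            ("s3", "AAACCCDDD", 9.0, False, "fed"),
            ("s4", "AAACCCDDD", 9.0, False, "fed"),
        ]
        n_base = len(infer_proteins(classified(db, base_rows), db))
        n_extra = len(infer_proteins(classified(db, extra_rows), db))
        assert n_extra <= n_base

    def test_shared_psms_keep_unambiguous_group_alive(self):
        # the 1a peptide has one PSM, but the absorbed 2b peptide's PSMs
        # push the sequence identification over the threshold; parsimony
        # then explains the 2b peptide without a separate gene group
        db = make_db(
            ("p1", "t1", "g1", "COMMONWWAAACCCDDD"),
            ("p2", "t2", "g1", "COMMONWWEEEFFFGGG"),
        )
        rows = [
            ("s1", "COMMONWW", 9.0, False, "fed"),  # 2b, 3 PSMs
            ("s2", "COMMONWW", 9.0, False, "fed"),
            ("s3", "COMMONWW", 9.0, False, "fed"),
            ("s4", "AAACCCDDD", 9.0, False, "fed"),  # 1a, only 1 PSM
        ]
        groups = infer_proteins(classified(db, rows), db)
        (g,) = groups
        assert g.evidence_tier == "unambiguous"
        assert g.member_protein_ids == {"p1"}
        assert "COMMONWW" in g.supporting_peptides
        assert g.psm_count == 4

    def test_weak_unambiguous_group_dropped_gene_group_survives(self):
        # 1a evidence on an isoform with a single PSM disappears; the 2a
        # peptide on the other two isoforms still yields a gene-model group
        db = make_db(
            ("p1", "t1", "g1", "COMMONWWAAACCCDDD"),
            ("p2", "t2", "g1", "COMMONWWEEEFFFGGG"),
            ("p3", "t3", "g1", "YYYYYYHHHHHHNNNN"),
        )
        rows = [
            ("s1", "COMMONWW", 9.0, False, "fed"),  # 2a, 3 PSMs
            ("s2", "COMMONWW", 9.0, False, "fed"),
            ("s3", "COMMONWW", 9.0, False, "fed"),
            ("s4", "YYYYYYHHHH", 9.0, False, "fed"),  # 1a, only 1 PSM
        ]
        groups = infer_proteins(classified(db, rows), db)
        tiers = [g.evidence_tier for g in groups]
        assert tiers == ["gene-model"]
        (g,) = groups
        assert g.member_protein_ids == {"p1", "p2"}
        assert g.psm_count == 3

    def test_no_group_below_min_psms(self, tiny_db, rng):
        peptides = ["TTTVVV", "AAAGGG", "HHHHLLL", "WWNDFGHTTYE"]
        rows = [
            (f"s{i}", peptides[int(rng.integers(4))], 5.0, False, "fed")
            for i in range(25)
        ]
        for min_psms in (1, 2, 3, 5):
            groups = infer_proteins(classified(tiny_db, rows), tiny_db,
                                    min_psms=min_psms)
            assert all(g.psm_count >= min_psms for g in groups)

    def test_deterministic_group_ids(self, tiny_db, rng):
        rows = [
            ("s1", "TTTVVV", 9.0, False, "fed"),
            ("s2", "TTTVVV", 9.0, False, "fed"),
            ("s3", "HHHHLLL", 9.0, False, "fed"),
            ("s4", "HHHHLLL", 9.0, False, "fed"),
        ]
        g1 = infer_proteins(classified(tiny_db, rows), tiny_db)
        g2 = infer_proteins(classified(tiny_db, rows), tiny_db)
        assert [g.group_id for g in g1] == [g.group_id for g in g2]
        assert [g.member_protein_ids for g in g1] == [
            g.member_protein_ids for g in g2
        ]


class TestIdentificationSummary:
    def _fixture(self, tiny_db):
        rows = [
            ("s1", "TTTVVV", 9.0, False, "fed"),    # 1a
            ("s2", "TTTVVV", 9.0, False, "fed"),
            ("s3", "AAAGGG", 9.0, False, "fed"),    # 1b
            ("s4", "AAAGGG", 9.0, False, "fed"),
            ("s5", "HHHHLLL", 9.0, False, "fed"),   # 3a
            ("s6", "HHHHLLL", 9.0, False, "fed"),
            ("s7", "WWNDFGHTTYE", 9.0, False, "fed"),  # 2b
            ("s8", "WWNDFGHTTYE", 9.0, False, "fed"),
        ]
        cls = classified(tiny_db, rows)
        groups = infer_proteins(cls, tiny_db)
        return cls, groups

    def test_census_matches_hand_enumeration(self, tiny_db):
        cls, groups = self._fixture(tiny_db)
        summary = identification_summary(groups, cls).set_index("evidence_class")
        assert summary.loc["1a", "n_proteins"] == 1
        assert summary.loc["1b", "n_proteins"] == 1
        assert summary.loc["3a", "n_proteins"] == 1
        assert summary.loc["2b", "n_proteins"] == 1
        assert summary.loc["target_total", "n_proteins"] == 4

    def test_total_equals_sum_of_class_rows(self, tiny_db):
        cls, groups = self._fixture(tiny_db)
        summary = identification_summary(groups, cls).set_index("evidence_class")
        class_rows = summary.loc[["1a", "1b", "2a", "2b", "3a", "3b"]]
        for col in ("n_spectra", "n_peptides", "n_proteins"):
            assert class_rows[col].sum() == summary.loc["target_total", col]

    def test_all_decoy_input_target_rows_zero(self, tiny_db):
        from hemoshotgun.db import build_decoy_db, concat_dbs

        full = concat_dbs(tiny_db, build_decoy_db(tiny_db))
        rows = [
            ("s1", "VVVTTT"[::1], 9.0, True, "fed"),
        ]
        # decoy of pE1 "MTTTVVVYYYW" reversed is "WYYYVVVTTTM"
        decoy_pep = "WYYYVVVTTT"
        cls = classify_psms(
            psm_frame([("s1", decoy_pep, 9.0, True, "fed"),
                       ("s2", decoy_pep, 9.0, True, "fed")]),
            full,
        )
        target_cls = cls[~cls["is_decoy"]]
        decoy_cls = cls[cls["is_decoy"]]
        tgt_groups = infer_proteins(target_cls, full)
        dec_groups = infer_proteins(decoy_cls, full)
        summary = identification_summary(
            tgt_groups, target_cls, dec_groups, decoy_cls
        ).set_index("evidence_class")
        assert summary.loc["target_total", "n_spectra"] == 0
        assert summary.loc["target_total", "n_proteins"] == 0
        assert summary.loc["decoy_total", "n_spectra"] == 2
        assert summary.loc["decoy_total", "n_proteins"] == 1
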