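"""Fragment matching and the count tables (summary, profiles, heatmap)."""

import pytest

from peptimine.activity import build_activity_db
from peptimine.digestion import digest
from peptimine.errors import ConsistencyError
from peptimine.matching import (
    BioactiveMatch,
    build_activity_profile,
    build_heatmap_matrix,
    build_summary,
    heatmap_long,
    match_fragments,
)
from peptimine.rules import ProteaseSpec, compile_pattern
from peptimine.sequences import ProteinRecord

SPEC = ProteaseSpec("t", "1.1.1.1", (compile_pattern("P1:[K]"),))


def test_exact_match_semantics():
    res = digest(ProteinRecord("P", "AKG"), SPEC, min_peptide_length=1)
    db = build_activity_db([("AK", "ACE inhibitor")])
    (m,) = match_fragments(res, db)
    assert m.peptide == "AK" and m.activities == {"ACE inhibitor"}


def test_disjoint_sets_give_no_matches():
    res = digest(ProteinRecord("P", "AKG"), SPEC)
    db = build_activity_db([("WW", "ACE inhibitor")])
    assert match_fragments(res, db) == []


def test_buried_database_peptide_does_not_match():
    """Only full released fragments count, not encrypted sub-sequences."""
    res = digest(ProteinRecord("P", "GAVLG"), SPEC)  # no K: one fragment
    db = build_activity_db([("AVL", "ACE inhibitor")])
    assert match_fragments(res, db) == []


def test_match_order_is_first_occurrence_then_sequence():
    res = digest(ProteinRecord("P", "GGKAAKGG"), SPEC)
    db = build_activity_db([("GG", "a"), ("AAK", "b"), ("GGK", "c")])
    assert [m.peptide for m in match_fragments(res, db)] == ["GGK", "AAK", "GG"]


def _mini_world():
    """Two proteins x one enzyme with hand-checkable counts."""
    recs = [ProteinRecord("P1", "GGKAAKGG"), ProteinRecord("P2", "AAKGGKWW")]
    db = build_activity_db(
        [("GG", "ACE inhibitor"), ("GG", "antioxidative"), ("AAK", "ACE inhibitor")]
    )
    results = [digest(r, SPEC) for r in recs]
    matches = [m for res in results for m in match_fragments(res, db)]
    return recs, db, results, matches


class TestSummary:
    def test_single_cell_table(self):
        res = digest(ProteinRecord("P1", "GGKAAKGG"), SPEC)
        db = build_activity_db([("GGK", "a"), ("AAK", "b")])
        table = build_summary([res], match_fragments(res, db))
        row = table.rows.iloc[0]
        assert (row.total_peptides, row.bioactive_peptides) == (3, 2)
        assert table.totals.iloc[0].total_peptides == 3

    def test_totals_are_additive(self):
        _, _, results, matches = _mini_world()
        table = build_summary(results, matches)
        assert table.totals.iloc[0].total_peptides == sum(table.rows.total_peptides)
        assert table.totals.iloc[0].bioactive_peptides == sum(table.rows.bioactive_peptides)

    def test_bioactive_never_exceeds_total(self):
        _, _, results, matches = _mini_world()
        rows = build_summary(results, matches).rows
        assert (rows.bioactive_peptides <= rows.total_peptides).all()

    def test_missing_cell_raises(self):
        recs, db, results, matches = _mini_world()
        other = ProteaseSpec("u", "1.1.1.2", (compile_pattern("P1:[W]"),))
        partial = results + [digest(recs[0], other)]  # P2 x u missing
        with pytest.raises(ConsistencyError, match="missing"):
            build_summary(partial, matches)

    def test_occurrence_counting_counts_positional_fragments(self):
        res = digest(ProteinRecord("P1", "GGKGGKGG"), SPEC)  # GGK, GGK, GG
        db = build_activity_db([("GGK", "a")])
        matches = match_fragments(res, db)
        distinct = build_summary([res], matches, counting="distinct").rows.iloc[0]
        occurrence = build_summary([res], matches, counting="occurrence").rows.iloc[0]
        assert (distinct.total_peptides, distinct.bioactive_peptides) == (2, 1)
        assert (occurrence.total_peptides, occurrence.bioactive_peptides) == (3, 2)


class TestActivityProfile:
    def test_multifunctional_peptide_counts_once_per_activity(self):
        m = BioactiveMatch("P1", "t", "GG", frozenset({"a", "b"}))
        prof = build_activity_profile([m], ["a", "b", "c"], "t")
        assert prof.counts == {"a": 1, "b": 1, "c": 0}
        assert prof.bioactive_total == 1

    def test_same_peptide_in_two_proteins_counts_twice(self):
        ms = [
            BioactiveMatch("P1", "t", "GG", frozenset({"a"})),
            BioactiveMatch("P2", "t", "GG", frozenset({"a"})),
        ]
        prof = build_activity_profile(ms, ["a"], "t")
        assert prof.counts["a"] == 2 and prof.bioactive_total == 2

    def test_counts_sum_at_least_bioactive_total(self):
        _, db, _, matches = _mini_world()
        prof = build_activity_profile(matches, sorted(db.vocabulary), "t")
        assert sum(prof.counts.values()) >= prof.bioactive_total


class TestHeatmap:
    def test_single_cell_matrix(self):
        m = BioactiveMatch("P1", "t", "GG", frozenset({"a"}))
        wide = build_heatmap_matrix([m], [("P1", "t")], ["a"])
        assert wide.shape == (1, 1) and wide.iloc[0, 0] == 1

    def test_all_zero_matches_keep_full_vocabulary(self):
        wide = build_heatmap_matrix([], [("P1", "t"), ("P2", "t")], ["a", "b"])
        assert wide.shape == (2, 2) and (wide.to_numpy() == 0).all()

    def test_marginals_reconcile_with_profiles(self):
        _, db, results, matches = _mini_world()
        vocab = sorted(db.vocabulary)
        cells = [(r.protein_id, r.protease_name) for r in results]
        wide = build_heatmap_matrix(matches, cells, vocab)
        prof = build_activity_profile(matches, vocab, "t")
        assert wide.sum(axis=0).to_dict() == prof.counts
        long = heatmap_long(wide)
        assert long["count"].sum() == wide.to_numpy().sum()

    def test_vocabulary_mismatch_raises(self):
        m = BioactiveMatch("P1", "t", "GG", frozenset({"zz"}))
        with pytest.raises(ConsistencyError, match="zz"):
            build_heatmap_matrix([m], [("P1", "t")], ["a"])


def test_planted_truth_recovered_exactly(small_panel):
    """End-to-end: engine digestion + matching equals the analytic truth."""
    from peptimine.digestion import digest as engine_digest

    for rec in small_panel.proteins:
        for spec in small_panel.enzymes:
            truth = small_panel.truth[(rec.id, spec.name)]
            res = engine_digest(rec, spec, small_panel.min_peptide_length)
            got = {m.peptide: m.activities for m in match_fragments(res, small_panel.db)}
            assert got == truth.matches
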