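"""Cleavage-pattern grammar, built-in enzymes and bond-matching semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle import oracle_sites, random_sequence, random_spec
from peptimine.errors import RuleSyntaxError
from peptimine.rules import (
    CleavagePattern,
    DEFAULT_CLASSES,
    ProteaseSpec,
    bond_matches,
    builtin_protease,
    compile_pattern,
    load_protease_file,
    serialize_pattern,
)


class TestCompilePattern:
    def test_simplest_legal_rule(self):
        pat = compile_pattern("P1:[KR]")
        assert pat.constraints == {"P1": frozenset("KR")}

    def test_p1_prime_constraint(self):
        pat = compile_pattern("P1:[K] P1':[P]")
        assert pat.constraints["P1'"] == frozenset("P")

    def test_named_class_and_union(self):
        pat = compile_pattern("P1:[KY]+<hydrophobic>")
        assert pat.constraints["P1"] == frozenset("KY") | DEFAULT_CLASSES["hydrophobic"]

    def test_empty_class_rejected(self):
        with pytest.raises(RuleSyntaxError, match="empty"):
            compile_pattern("P1:[]")

    def test_missing_p1_rejected(self):
        with pytest.raises(RuleSyntaxError, match="P1"):
            compile_pattern("P2:[A]")

    def test_syntax_error_reports_column(self):
        with pytest.raises(RuleSyntaxError) as exc:
            compile_pattern("P1:[K] Q9:[A]")
        assert exc.value.column == 8

    def test_unknown_class_rejected(self):
        with pytest.raises(RuleSyntaxError, match="nosuch"):
            compile_pattern("P1:<nosuch>")

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(RuleSyntaxError):
            compile_pattern("P1:[KB]")


class TestBuiltins:
    def test_ficin_has_arginine_p1(self, ficin):
        assert any(p.constraints["P1"] == frozenset("R") for p in ficin.patterns)
        assert ficin.ec_number == "3.4.22.3"

    def test_bromelain_p1_contains_lysine_and_tyrosine(self, bromelain):
        p1 = bromelain.p1_union()
        assert {"K", "Y"} <= p1
        assert DEFAULT_CLASSES["hydrophobic"] <= p1
        assert bromelain.ec_number == "3.4.22.32"

    def test_papain_targets_hydrophobic_motifs(self, papain):
        assert any(
            p.constraints["P1"] == DEFAULT_CLASSES["hydrophobic"]
            for p in papain.patterns
        )
        assert papain.ec_number == "3.4.22.2"

    def test_stem_bromelain_alias(self, bromelain):
        assert builtin_protease("stem bromelain") == bromelain

    def test_unknown_enzyme_lists_available(self):
        with pytest.raises(KeyError, match="papain"):
            builtin_protease("trypsin")


class TestBondMatches:
    def test_direct_p1_match(self):
        spec = ProteaseSpec("t", "1.1.1.1", (compile_pattern("P1:[K]"),))
        assert bond_matches(spec, "AKG", 2) is True
        assert bond_matches(spec, "AKG", 1) is False

    def test_p1_prime_constraint(self):
        spec = ProteaseSpec("t", "1.1.1.1", (compile_pattern("P1:[K] P1':[P]"),))
        assert bond_matches(spec, "AKPG", 2) is True
        assert bond_matches(spec, "AKGG", 2) is False

    def test_off_terminus_context_fails(self):
        spec = ProteaseSpec("t", "1.1.1.1", (compile_pattern("P2:[F] P1:[K]"),))
        assert bond_matches(spec, "FKA", 2) is True
        assert bond_matches(spec, "KA", 1) is False  # no P2 residue exists

    def test_out_of_range_bond_rejected(self):
        spec = ProteaseSpec("t", "1.1.1.1", (compile_pattern("P1:[K]"),))
        with pytest.raises(ValueError):
            bond_matches(spec, "AK", 2)
        with pytest.raises(ValueError):
            bond_matches(spec, "AK", 0)


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000), length=st.integers(2, 60))
def test_enlarging_a_class_never_unmatches_a_bond(seed, length):
    rng = np.random.default_rng(seed)
    spec = random_spec(rng)
    seq = random_sequence(rng, length)
    # enlarge every P1 set by one arbitrary residue
    bigger = ProteaseSpec(
        spec.name,
        spec.ec_number,
        tuple(
            CleavagePattern({**p.constraints, "P1": p.constraints["P1"] | {"G"}})
            for p in spec.patterns
        ),
    )
    for bond in range(1, length):
        if bond_matches(spec, seq, bond):
            assert bond_matches(bigger, seq, bond)


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000), length=st.integers(2, 60))
def test_pattern_union_semantics(seed, length):
    rng = np.random.default_rng(seed)
    a, b = random_spec(rng, "a"), random_spec(rng, "b")
    union = ProteaseSpec("u", "1.1.1.1", a.patterns + b.patterns)
    seq = random_sequence(rng, length)
    for bond in range(1, length):
        assert bond_matches(union, seq, bond) == (
            bond_matches(a, seq, bond) or bond_matches(b, seq, bond)
        )


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_serialize_then_recompile_matches_identically(seed):
    rng = np.random.default_rng(seed)
    spec = random_spec(rng)
    rebuilt = ProteaseSpec(
        spec.name,
        spec.ec_number,
        tuple(compile_pattern(serialize_pattern(p)) for p in spec.patterns),
    )
    seq = random_sequence(rng, 50)
    assert oracle_sites(seq, spec) == oracle_sites(seq, rebuilt)


def test_rule_file_round_trip(tmp_path, bromelain):
    f = tmp_path / "brom.rules"
    f.write_text(
        "# stem bromelain approximation\n"
        "name=bromelain\n"
        "ec=3.4.22.32\n"
        "P1:[KY]+<hydrophobic>\n"
    )
    assert load_protease_file(f) == bromelain


def test_rule_file_requires_headers(tmp_path):
    f = tmp_path / "anon.rules"
    f.write_text("P1:[K]\n")
    with pytest.raises(RuleSyntaxError, match="name"):
        load_protease_file(f)
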