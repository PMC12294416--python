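"""Cleavage-specificity grammar and built-in protease rule sets.

Positions follow Schechter–Berger nomenclature: for the bond between
residues i and i+1 (residues numbered from 1, bonds 1..L-1), P1 is
residue i, P1' is residue i+1, P2 is residue i-1, and so on.  Cleavage
is always C-terminal to P1.  A pattern is a conjunction of per-position
residue-set constraints; a protease cuts a bond if ANY of its patterns
matches.  A constraint that refers to a position beyond either terminus
fails its pattern (no wildcard padding).

Rule text grammar (one pattern per string)::

    pattern    := constraint (whitespace constraint)*
    constraint := position ":" class
    position   := "P4" | "P3" | "P2" | "P1" | "P1'" | "P2'"
    class      := atom ("+" atom)*
    atom       := "[" residue+ "]" | "<" name ">"

e.g. ``P2:[AVLIFWY] P1:[KR]`` or ``P1:[KY]+<hydrophobic>``.  Named
classes default to the table below and can be redefined per call.

The built-in specs for papain (EC 3.4.22.2), ficin (EC 3.4.22.3) and
stem bromelain (EC 3.4.22.32) encode the qualitative specificities
reported for these plant cysteine proteases: papain prefers hydrophobic
motifs (bulky hydrophobic P2 with basic P1, or hydrophobic P1), ficin
favours arginine at P1 plus aromatic sites, and bromelain cleaves
adjacent to lysine, tyrosine and hydrophobic residues.  They are
explicit, documented approximations of qualitative literature
statements — NOT byte-level reproductions of any external tool's
internal encodings — and every built-in can be overridden by a user
rule file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from peptimine.errors import RuleSyntaxError
from peptimine.sequences import CANONICAL_ALPHABET

#: Recognised relative positions and their offset from the P1 residue.
POSITION_OFFSETS: dict[str, int] = {
    "P4": -3,
    "P3": -2,
    "P2": -1,
    "P1": 0,
    "P1'": 1,
    "P2'": 2,
}

#: Default named residue classes; users may pass their own mapping.
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIFWYM"),
    "aromatic": frozenset("FWY"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
    "aliphatic": frozenset("AVLI"),
}

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


@dataclass(frozen=True)
class CleavagePattern:
    """Conjunction of per-position residue-set constraints; P1 mandatory."""

    constraints: Mapping[str, frozenset[str]]

    def __post_init__(self):
        if "P1" not in self.constraints:
            raise RuleSyntaxError("pattern must constrain P1")
        for pos, residues in self.constraints.items():
            if pos not in POSITION_OFFSETS:
                raise RuleSyntaxError(f"unknown position {pos!r}")
            if not residues:
                raise RuleSyntaxError(f"empty residue class at {pos}")
            bad = set(residues) - CANONICAL_ALPHABET
            if bad:
                raise RuleSyntaxError(
                    f"non-canonical residue(s) {sorted(bad)} at {pos}"
                )
        # freeze into a plain dict so equality/hash are well-defined
        object.__setattr__(self, "constraints", dict(self.constraints))

    def __hash__(self):
        return hash(tuple(sorted((p, tuple(sorted(r))) for p, r in self.constraints.items())))


@dataclass(frozen=True)
class ProteaseSpec:
    """A named enzyme: a bond is cut if ANY pattern matches."""

    name: str
    ec_number: str
    patterns: tuple[CleavagePattern, ...]

    def __post_init__(self):
        if not self.name:
            raise ValueError("protease name must be nonempty")
        if not _EC_RE.match(self.ec_number):
            raise ValueError(f"malformed EC number {self.ec_number!r}")
        if not self.patterns:
            raise ValueError("protease needs at least one pattern")
        object.__setattr__(self, "patterns", tuple(self.patterns))

    def p1_union(self) -> frozenset[str]:
        """Union of all P1 residue sets (every residue the enzyme can cut after)."""
        out: set[str] = set()
        for p in self.patterns:
            out |= p.constraints["P1"]
        return frozenset(out)


# --- pattern mini-language ------------------------------------------------

_TOKEN_RE = re.compile(r"\S+")
# position, then ':' then one-or-more atoms joined by '+'
_CONSTRAINT_RE = re.compile(
    r"^(?P<pos>P[1-4]'?)\:(?P<cls>(\[[A-Za-z]*\]|<[A-Za-z_]+>)(\+(\[[A-Za-z]*\]|<[A-Za-z_]+>))*)$"
)
_ATOM_RE = re.compile(r"\[([A-Za-z]*)\]|<([A-Za-z_]+)>")


def _resolve_class(cls_text: str, classes: Mapping[str, frozenset[str]], column: int) -> frozenset[str]:
    residues: set[str] = set()
    for m in _ATOM_RE.finditer(cls_text):
        if m.group(1) is not None:
            if not m.group(1):
                raise RuleSyntaxError("empty residue class '[]'", column + m.start())
            residues |= set(m.group(1).upper())
        else:
            name = m.group(2)
            if name not in classes:
                raise RuleSyntaxError(f"unknown class <{name}>", column + m.start())
            residues |= set(classes[name])
    return frozenset(residues)


def compile_pattern(
    text: str, classes: Mapping[str, frozenset[str]] | None = None
) -> CleavagePattern:
    """Compile rule text like ``"P2:[AVLIFWY] P1:[KR]"`` into a pattern.

    Raises :class:`RuleSyntaxError` (with a column number) on syntax
    errors, empty classes, unknown positions/classes, or a missing P1.
    """
    classes = dict(DEFAULT_CLASSES if classes is None else classes)
    text = text.replace("′", "'")  # accept the typographic prime
    constraints: dict[str, frozenset[str]] = {}
    matched_any = False
    for tok in _TOKEN_RE.finditer(text):
        matched_any = True
        m = _CONSTRAINT_RE.match(tok.group(0))
        if not m:
            raise RuleSyntaxError(
                f"cannot parse constraint {tok.group(0)!r}", tok.start() + 1
            )
        pos = m.group("pos")
        if pos in constraints:
            raise RuleSyntaxError(f"position {pos} constrained twice", tok.start() + 1)
        constraints[pos] = _resolve_class(m.group("cls"), classes, tok.start() + 1)
    if not matched_any:
        raise RuleSyntaxError("empty pattern", 1)
    return CleavagePattern(constraints)


def serialize_pattern(pattern: CleavagePattern) -> str:
    """Render a pattern back into canonical rule text."""
    order = list(POSITION_OFFSETS)
    parts = []
    for pos in order:
        if pos in pattern.constraints:
            parts.append(f"{pos}:[{''.join(sorted(pattern.constraints[pos]))}]")
    return " ".join(parts)


def bond_matches(spec: ProteaseSpec, sequence: str, bond_index: int) -> bool:
    """True iff some pattern of *spec* matches the bond at *bond_index*.

    Bonds are numbered 1..L-1; bond i separates residues i and i+1
    (1-based).  Raises ``ValueError`` for a bond index out of range.
    """
    n = len(sequence)
    if not 1 <= bond_index <= n - 1:
        raise ValueError(f"bond index {bond_index} out of range for length {n}")
    p1_idx = bond_index - 1  # 0-based index of the P1 residue
    for pattern in spec.patterns:
        for pos, residues in pattern.constraints.items():
            idx = p1_idx + POSITION_OFFSETS[pos]
            if not (0 <= idx < n) or sequence[idx] not in residues:
                break
        else:
            return True
    return False


# --- built-in enzymes -----------------------------------------------------

def _builtin_table(classes: Mapping[str, frozenset[str]]) -> dict[str, ProteaseSpec]:
    def pat(text: str) -> CleavagePattern:
        return compile_pattern(text, classes)

    return {
        "papain": ProteaseSpec(
            name="papain",
            ec_number="3.4.22.2",
            patterns=(pat("P2:<hydrophobic> P1:[KR]"), pat("P1:<hydrophobic>")),
        ),
        "ficin": ProteaseSpec(
            name="ficin",
            ec_number="3.4.22.3",
            patterns=(pat("P1:[R]"), pat("P1:[FY]")),
        ),
        "bromelain": ProteaseSpec(
            name="bromelain",
            ec_number="3.4.22.32",
            patterns=(pat("P1:[KY]+<hydrophobic>"),),
        ),
    }


#: Canonical names of the built-in enzymes.
BUILTIN_NAMES = ("papain", "ficin", "bromelain")

_ALIASES = {"stem bromelain": "bromelain", "stem_bromelain": "bromelain"}


def builtin_protease(
    name: str, classes: Mapping[str, frozenset[str]] | None = None
) -> ProteaseSpec:
    """Return the documented default spec for a built-in enzyme.

    ``name`` is case-insensitive; "stem bromelain" is accepted as an
    alias for bromelain.  Unknown names raise ``KeyError`` listing the
    available enzymes.
    """
    classes = DEFAULT_CLASSES if classes is None else classes
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    table = _builtin_table(classes)
    if key not in table:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins are: {', '.join(BUILTIN_NAMES)}"
        )
    return table[key]


def load_protease_file(
    path: str | Path, classes: Mapping[str, frozenset[str]] | None = None
) -> ProteaseSpec:
    """Read an enzyme from a plain-text rule file.

    Format: optional ``# comment`` lines, ``name=...`` and ``ec=...``
    headers, then one pattern per line in the :func:`compile_pattern`
    grammar.
    """
    name = ""
    ec = ""
    patterns: list[CleavagePattern] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("name="):
            name = line[5:].strip()
        elif line.lower().startswith("ec="):
            ec = line[3:].strip()
        else:
            try:
                patterns.append(compile_pattern(line, classes))
            except RuleSyntaxError as e:
                raise RuleSyntaxError(f"{path}:{lineno}: {e}") from e
    if not name:
        raise RuleSyntaxError(f"{path}: missing 'name=' header")
    if not ec:
        raise RuleSyntaxError(f"{path}: missing 'ec=' header")
    return ProteaseSpec(name=name, ec_number=ec, patterns=tuple(patterns))


def resolve_enzyme(
    token: str, classes: Mapping[str, frozenset[str]] | None = None
) -> ProteaseSpec:
    """Resolve an enzyme token: a built-in name or a rule-file path."""
    try:
        return builtin_protease(token, classes)
    except KeyError:
        if Path(token).exists():
            return load_protease_file(token, classes)
        raise
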