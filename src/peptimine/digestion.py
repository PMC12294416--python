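"""Exhaustive single-protease digestion under complete hydrolysis.

Every bond matching the enzyme's recognition patterns is cleaved
simultaneously — the idealised regime in which released fragments
contain no internal cleavage site.  "Peptides" counts DISTINCT
fragment sequences of length >= ``min_peptide_length`` (default 2:
free amino acids are not peptides); both the counting unit and the
length floor are configurable because different catalogue tools count
differently.
"""

from __future__ import annotations

from dataclasses import dataclass

from peptimine.rules import ProteaseSpec, bond_matches
from peptimine.sequences import ProteinRecord


@dataclass(frozen=True)
class Fragment:
    """A positional slice [start, end) of the parent protein (0-based)."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad fragment bounds [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length disagrees with bounds")


@dataclass(frozen=True)
class DigestResult:
    """Fragments and distinct peptides released from one protein by one enzyme."""

    protein_id: str
    protease_name: str
    sites: tuple[int, ...]          # cut bond indices, 1-based, sorted
    fragments: tuple[Fragment, ...]  # positional, N->C order
    peptides: frozenset[str]         # distinct sequences, length >= min_peptide_length
    min_peptide_length: int = 2

    @property
    def total_peptides(self) -> int:
        return len(self.peptides)


def find_sites(record: ProteinRecord, spec: ProteaseSpec) -> list[int]:
    """All bond indices (1..L-1) cut by *spec*, ascending."""
    seq = record.sequence
    return [i for i in range(1, len(seq)) if bond_matches(spec, seq, i)]


def digest(
    record: ProteinRecord, spec: ProteaseSpec, min_peptide_length: int = 2
) -> DigestResult:
    """Complete hydrolysis of *record* by *spec*.

    Fragments are the maximal uncut substrings between consecutive cut
    sites (plus the termini); their concatenation reconstructs the
    input, and the fragment count equals the site count plus one.
    """
    if min_peptide_length < 1:
        raise ValueError("min_peptide_length must be >= 1")
    seq = record.sequence
    sites = find_sites(record, spec)
    bounds = [0] + sites + [len(seq)]
    fragments = tuple(
        Fragment(record.id, a, b, seq[a:b]) for a, b in zip(bounds, bounds[1:])
    )
    peptides = frozenset(
        f.sequence for f in fragments if len(f.sequence) >= min_peptide_length
    )
    return DigestResult(
        protein_id=record.id,
        protease_name=spec.name,
        sites=tuple(sites),
        fragments=fragments,
        peptides=peptides,
        min_peptide_length=min_peptide_length,
    )


def redigest_is_stable(result: DigestResult, spec: ProteaseSpec) -> bool:
    """True iff re-digesting every fragment leaves it unchanged.

    Complete hydrolysis is a fixed point: a released fragment contains
    no internal bond the enzyme would cut.
    """
    for frag in result.fragments:
        seq = frag.sequence
        for i in range(1, len(seq)):
            if bond_matches(spec, seq, i):
                return False
    return True
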