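"""Protein sequence I/O and validation.

Substrate sequences enter the pipeline as plain FASTA.  The accepted
alphabet is the 20 canonical one-letter amino-acid codes; ambiguity
codes (B, J, O, U, X, Z) are rejected by default with a located error,
or — under ``permissive=True`` — mapped to the sentinel residue ``X``,
which never satisfies a cleavage pattern and disqualifies any fragment
containing it from database matching.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from peptimine.errors import FastaParseError, SequenceValidationError

#: The 20 canonical residues, the only letters allowed in substrates.
CANONICAL_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes that are rejected (or mapped to the sentinel).
AMBIGUITY_CODES = frozenset("BJOUXZ")

#: Residue that matches no cleavage pattern; stands in for ambiguity codes.
SENTINEL_RESIDUE = "X"


@dataclass(frozen=True)
class ProteinRecord:
    """One input protein: identifier, free-text description, residue string."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(record_id: str, sequence: str, permissive: bool) -> str:
    if not sequence:
        raise FastaParseError(f"record {record_id!r} has an empty sequence")
    chars = []
    for pos, ch in enumerate(sequence, start=1):
        if ch in CANONICAL_ALPHABET:
            chars.append(ch)
        elif permissive and ch in AMBIGUITY_CODES:
            chars.append(SENTINEL_RESIDUE)
        else:
            raise SequenceValidationError(record_id, pos, ch)
    return "".join(chars)


def make_record(
    record_id: str, sequence: str, description: str = "", permissive: bool = False
) -> ProteinRecord:
    """Build a validated :class:`ProteinRecord` (uppercases the sequence)."""
    seq = _validate_sequence(record_id, sequence.upper(), permissive)
    return ProteinRecord(id=record_id, sequence=seq, description=description)


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into validated records, in file order.

    Sequences are uppercased and internal whitespace removed.  Raises
    :class:`FastaParseError` for malformed input (no header line, empty
    record), :class:`SequenceValidationError` for a residue outside the
    alphabet, and a duplicate-id error if two entries share an id.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaParseError(f"{path}: not FASTA — first record has no '>' header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with io.StringIO(text) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
            seen.add(entry.id)
            raw = str(entry.seq).replace(" ", "").replace("\t", "")
            desc = entry.description
            if desc.startswith(entry.id):
                desc = desc[len(entry.id):].strip()
            records.append(make_record(entry.id, raw, desc, permissive=permissive))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, sequences wrapped at 60 columns.

    ``read_fasta(write_fasta(x)) == x`` for any valid record list.
    """
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as handle:
        SeqIO.write(seqrecords, handle, "fasta")
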