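"""Peptide -> activity database loading, saving and merging.

The database is a local TSV with columns ``peptide``, ``activity`` and
optional ``source_id`` — one row per (peptide, activity) pair, the
shape of an export from any bioactive-peptide catalogue.  Activity
labels are matched verbatim after whitespace trimming; no ontology
normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from peptimine.errors import SchemaError, SequenceValidationError
from peptimine.sequences import CANONICAL_ALPHABET


@dataclass
class ActivityDB:
    """Map peptide sequence -> set of activity labels.

    ``vocabulary`` lists every label present, in first-appearance order.
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self):
        for pep, acts in self.entries.items():
            if not acts:
                raise ValueError(f"peptide {pep!r} has an empty activity set")
        union = set().union(*self.entries.values()) if self.entries else set()
        if set(self.vocabulary) != union:
            raise ValueError("vocabulary does not equal the union of entry labels")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.entries


def _check_peptide(peptide: str, row: int) -> str:
    pep = peptide.strip().upper()
    if not pep:
        raise SequenceValidationError(f"row {row}", 1, "")
    for pos, ch in enumerate(pep, start=1):
        if ch not in CANONICAL_ALPHABET:
            raise SequenceValidationError(f"row {row} ({pep!r})", pos, ch)
    return pep


def build_activity_db(pairs: list[tuple[str, str]]) -> ActivityDB:
    """Aggregate (peptide, activity) pairs into an :class:`ActivityDB`.

    Duplicate pairs collapse; vocabulary order is first appearance.
    """
    entries: dict[str, set[str]] = {}
    vocab: list[str] = []
    for row, (peptide, activity) in enumerate(pairs, start=1):
        pep = _check_peptide(peptide, row)
        act = activity.strip()
        if not act:
            raise SchemaError(f"row {row}: empty activity label")
        entries.setdefault(pep, set()).add(act)
        if act not in vocab:
            vocab.append(act)
    return ActivityDB(
        entries={p: frozenset(a) for p, a in entries.items()},
        vocabulary=tuple(vocab),
    )


def load_activity_db(path: str | Path) -> ActivityDB:
    """Load a TSV (columns: peptide, activity, [source_id]) into a DB."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"peptide", "activity"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return build_activity_db(list(zip(df["peptide"], df["activity"])))


def save_activity_db(db: ActivityDB, path: str | Path) -> None:
    """Write a DB back to TSV (peptide, activity, source_id), sorted rows."""
    rows = [
        {"peptide": pep, "activity": act, "source_id": ""}
        for pep in sorted(db.entries)
        for act in sorted(db.entries[pep])
    ]
    pd.DataFrame(rows, columns=["peptide", "activity", "source_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def merge_dbs(a: ActivityDB, b: ActivityDB) -> ActivityDB:
    """Entry-wise union; commutative and idempotent up to vocabulary order."""
    entries: dict[str, frozenset[str]] = dict(a.entries)
    for pep, acts in b.entries.items():
        entries[pep] = entries.get(pep, frozenset()) | acts
    vocab = list(a.vocabulary)
    for label in b.vocabulary:
        if label not in vocab:
            vocab.append(label)
    return ActivityDB(entries=entries, vocabulary=tuple(vocab))
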