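"""Score-table ingestion and threshold classification.

Peptide scores come from an external ranker as a two-column TSV
(``peptide``, ``score`` in [0, 1]); the ranking model itself is never
computed here.  A peptide is classified bioactive when its score is
greater than or equal to the threshold (default 0.50, inclusive).
Unique sequences are scored once and joined back to their protein x
enzyme provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from peptimine.errors import ConsistencyError, SchemaError
from peptimine.matching import TOTAL_ROW_ID

#: Default classification threshold (inclusive).
DEFAULT_THRESHOLD = 0.50


@dataclass(frozen=True)
class ScoreRecord:
    peptide: str
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"peptide {self.peptide!r}: score {self.score} outside [0, 1]"
            )


def load_scores(path: str | Path) -> list[ScoreRecord]:
    """Load a ``peptide<TAB>score`` table; duplicates and bad scores rejected."""
    # keep_default_na=False: peptides like "NA" are sequences, not missing
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"peptide", "score"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df["peptide"][df["peptide"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicate peptide(s) {sorted(set(dup))}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(ScoreRecord(row.peptide.strip().upper(), float(row.score)))
        except ValueError as e:
            raise SchemaError(f"{path}: line {i}: {e}") from e
    return records


def classify_bioactive(
    records: Sequence[ScoreRecord], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[ScoreRecord], list[ScoreRecord]]:
    """Partition records into (bioactive, inactive) at an INCLUSIVE threshold.

    ``score >= threshold`` is bioactive; input order is preserved in
    each half and the two halves always sum to the input size.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    bioactive = [r for r in records if r.score >= threshold]
    inactive = [r for r in records if r.score < threshold]
    return bioactive, inactive


def per_protein_bioactive_counts(
    bioactive: Iterable[ScoreRecord],
    provenance: Mapping[tuple[str, str], Iterable[str]],
    all_scored: Iterable[ScoreRecord] | None = None,
) -> pd.DataFrame:
    """Count above-threshold peptides per protein x enzyme cell.

    ``provenance`` maps (protein_id, enzyme) -> peptides released in
    that digest.  Columns: protein_id, enzyme, bioactive_count; one
    grand-total row per enzyme is appended.  If ``all_scored`` is
    given, every scored peptide must be traceable to at least one cell
    (orphans raise :class:`ConsistencyError`).
    """
    cell_peptides = {k: frozenset(v) for k, v in provenance.items()}
    if all_scored is not None:
        known = frozenset().union(*cell_peptides.values()) if cell_peptides else frozenset()
        orphans = sorted({r.peptide for r in all_scored} - known)
        if orphans:
            raise ConsistencyError(
                f"scored peptide(s) not traceable to any digest: {orphans[:5]}"
            )
    hits = {r.peptide for r in bioactive}
    rows = [
        {
            "protein_id": protein,
            "enzyme": enzyme,
            "bioactive_count": len(hits & peps),
        }
        for (protein, enzyme), peps in cell_peptides.items()
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "enzyme", "bioactive_count"])
    totals = df.groupby("enzyme", sort=False)[["bioactive_count"]].sum().reset_index()
    totals.insert(0, "protein_id", TOTAL_ROW_ID)
    return pd.concat([df, totals], ignore_index=True)
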