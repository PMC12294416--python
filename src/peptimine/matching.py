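"""Search released fragments against the activity database; build count tables.

Matching is exact full-fragment membership: a released peptide counts
only if its complete sequence is a database key.  A database dipeptide
buried inside a longer fragment does NOT count — encrypted-motif
scanning is a deliberate non-goal.  Peptides containing the sentinel
residue (permissive ambiguity handling) are never matched.

Counting conventions (configurable through ``counting``):

* ``distinct`` (default) — a peptide sequence counts once per
  protein x enzyme, however many times it occurs positionally;
* ``occurrence`` — positional fragments are counted with multiplicity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from peptimine.activity import ActivityDB
from peptimine.digestion import DigestResult
from peptimine.errors import ConsistencyError
from peptimine.sequences import CANONICAL_ALPHABET

#: Label of the appended per-enzyme grand-total row.
TOTAL_ROW_ID = "in total"


@dataclass(frozen=True)
class BioactiveMatch:
    """One released peptide found verbatim in the activity database."""

    protein_id: str
    protease_name: str
    peptide: str
    activities: frozenset[str]

    def __post_init__(self):
        if not self.activities:
            raise ValueError("a match must carry at least one activity")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-enzyme activity counts over distinct (protein, peptide) pairs."""

    protease_name: str
    counts: dict[str, int]   # full vocabulary, zeros included
    bioactive_total: int     # distinct (protein, peptide) pairs with >= 1 activity


def match_fragments(result: DigestResult, db: ActivityDB) -> list[BioactiveMatch]:
    """Distinct released peptides whose full sequence is a database key.

    Deterministic order: position of first occurrence along the parent,
    then sequence.  Fragments with non-canonical residues are skipped.
    """
    first_pos: dict[str, int] = {}
    for frag in result.fragments:
        first_pos.setdefault(frag.sequence, frag.start)
    hits = [
        pep
        for pep in result.peptides
        if pep in db.entries and set(pep) <= CANONICAL_ALPHABET
    ]
    hits.sort(key=lambda p: (first_pos.get(p, 0), p))
    return [
        BioactiveMatch(result.protein_id, result.protease_name, pep, db.entries[pep])
        for pep in hits
    ]


def _cell_totals(result: DigestResult, counting: str) -> int:
    if counting == "distinct":
        return len(result.peptides)
    if counting == "occurrence":
        return sum(
            1 for f in result.fragments if len(f.sequence) >= result.min_peptide_length
        )
    raise ValueError(f"unknown counting mode {counting!r}")


def _cell_bioactive(
    result: DigestResult, matched: set[str], counting: str
) -> int:
    if counting == "distinct":
        return len(matched)
    return sum(1 for f in result.fragments if f.sequence in matched)


@dataclass(frozen=True)
class SummaryTable:
    """Per protein x enzyme totals plus per-enzyme grand totals.

    ``rows`` columns: protein_id, enzyme, total_peptides,
    bioactive_peptides; ``totals`` has one row per enzyme labelled
    ``in total``.
    """

    rows: pd.DataFrame
    totals: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Rows with the grand-total rows appended (the printable table)."""
        return pd.concat([self.rows, self.totals], ignore_index=True)


def build_summary(
    results: Sequence[DigestResult],
    matches: Sequence[BioactiveMatch],
    counting: str = "distinct",
) -> SummaryTable:
    """Tabulate total and bioactive peptide counts per protein x enzyme.

    Requires exactly one :class:`DigestResult` per (protein, enzyme)
    cell; matches must belong to one of those cells.
    """
    cells: dict[tuple[str, str], DigestResult] = {}
    for r in results:
        key = (r.protein_id, r.protease_name)
        if key in cells:
            raise ConsistencyError(f"duplicate digest for {key}")
        cells[key] = r
    matched: dict[tuple[str, str], set[str]] = {k: set() for k in cells}
    for m in matches:
        key = (m.protein_id, m.protease_name)
        if key not in cells:
            raise ConsistencyError(f"match for missing protein x enzyme cell {key}")
        matched[key].add(m.peptide)

    proteins = list(dict.fromkeys(r.protein_id for r in results))
    enzymes = list(dict.fromkeys(r.protease_name for r in results))
    for p in proteins:
        for e in enzymes:
            if (p, e) not in cells:
                raise ConsistencyError(f"missing digest for protein {p!r} x enzyme {e!r}")

    rows = []
    for p in proteins:
        for e in enzymes:
            r = cells[(p, e)]
            total = _cell_totals(r, counting)
            bio = _cell_bioactive(r, matched[(p, e)], counting)
            rows.append(
                {"protein_id": p, "enzyme": e, "total_peptides": total,
                 "bioactive_peptides": bio}
            )
    rows_df = pd.DataFrame(
        rows, columns=["protein_id", "enzyme", "total_peptides", "bioactive_peptides"]
    )
    totals_df = (
        rows_df.groupby("enzyme", sort=False)[["total_peptides", "bioactive_peptides"]]
        .sum()
        .reset_index()
    )
    totals_df.insert(0, "protein_id", TOTAL_ROW_ID)
    return SummaryTable(rows=rows_df, totals=totals_df)


def build_activity_profile(
    matches: Iterable[BioactiveMatch],
    vocabulary: Sequence[str],
    protease_name: str,
) -> ActivityProfile:
    """Per-activity counts for one enzyme over distinct (protein, peptide) pairs.

    A multifunctional peptide contributes once per activity per protein,
    so per-activity counts may sum above ``bioactive_total``.  Labels
    absent from the matches report 0.
    """
    counts: Counter[str] = Counter()
    pairs: set[tuple[str, str]] = set()
    for m in matches:
        if m.protease_name != protease_name:
            continue
        pair = (m.protein_id, m.peptide)
        if pair in pairs:
            continue
        pairs.add(pair)
        for act in m.activities:
            if act not in vocabulary:
                raise ConsistencyError(
                    f"activity {act!r} not in the supplied vocabulary"
                )
            counts[act] += 1
    return ActivityProfile(
        protease_name=protease_name,
        counts={label: counts.get(label, 0) for label in vocabulary},
        bioactive_total=len(pairs),
    )


def build_heatmap_matrix(
    matches: Sequence[BioactiveMatch],
    cells: Sequence[tuple[str, str]],
    vocabulary: Sequence[str],
) -> pd.DataFrame:
    """Wide count matrix: rows = protein x enzyme cells, columns = activities.

    Every supplied cell appears (all-zero rows included) and columns
    cover the full vocabulary, so row/column marginals reconcile with
    the summary table and per-enzyme activity profiles.
    """
    if len(set(cells)) != len(cells):
        raise ConsistencyError("duplicate protein x enzyme cell")
    counts: dict[tuple[str, str], Counter[str]] = {c: Counter() for c in cells}
    seen: set[tuple[str, str, str]] = set()
    for m in matches:
        key = (m.protein_id, m.protease_name)
        if key not in counts:
            raise ConsistencyError(f"match for missing cell {key}")
        if (m.protein_id, m.protease_name, m.peptide) in seen:
            continue
        seen.add((m.protein_id, m.protease_name, m.peptide))
        for act in m.activities:
            if act not in vocabulary:
                raise ConsistencyError(f"activity {act!r} not in vocabulary")
            counts[key][act] += 1
    index = pd.MultiIndex.from_tuples(cells, names=["protein_id", "enzyme"])
    data = [[counts[c].get(label, 0) for label in vocabulary] for c in cells]
    return pd.DataFrame(data, index=index, columns=list(vocabulary))


def heatmap_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide heatmap matrix into (protein_id, enzyme, activity, count)."""
    long = wide.stack().rename("count").reset_index()
    long.columns = ["protein_id", "enzyme", "activity", "count"]
    return long
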