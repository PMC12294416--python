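"""Synthetic proteins, activity databases and score tables with known truth.

Every pipeline stage can be tested without downloads: proteins are
random scaffolds with bioactive motifs planted in cleavable contexts,
the activity database mixes those motifs with decoys guaranteed never
to be released, and score tables carry a constructed number of
above-threshold entries.

Ground truth is computed at generation time by a naive per-bond
scanner coded independently of the digestion engine (it never calls
:mod:`peptimine.digestion`), so the end-to-end recovery test is a
genuine two-implementation cross-check.

Release guarantee.  A motif planted for an enzyme is built so that

* every residue except the last avoids the enzyme's union of P1 sets
  (no internal bond can ever be cut, whatever the context), and
* the last residue, and the anchor residue inserted before the motif,
  each belong to a pattern constraining P1 only (both boundary bonds
  are cut regardless of context).

Complete hydrolysis therefore releases the motif exactly, by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from peptimine.activity import ActivityDB, build_activity_db
from peptimine.errors import PlacementError
from peptimine.rules import BUILTIN_NAMES, ProteaseSpec, builtin_protease
from peptimine.scoring import ScoreRecord
from peptimine.sequences import CANONICAL_ALPHABET, ProteinRecord

#: Activity labels used by default panels (drawn from the vocabulary of
#: peptide catalogues: enzyme-inhibitory, antioxidant, etc.).
DEFAULT_ACTIVITY_LABELS = (
    "ACE inhibitor",
    "dipeptidyl peptidase IV inhibitor",
    "antioxidative",
    "dipeptidyl peptidase III inhibitor",
    "renin inhibitor",
    "alpha-glucosidase inhibitor",
    "antithrombotic",
    "antiamnestic",
    "neuropeptide",
    "hypotensive",
    "anticancer",
    "antibacterial",
)

_ALPHABET = sorted(CANONICAL_ALPHABET)

# window offsets relative to the bond's 0-based gap index (bond i sits
# immediately before sequence[i]); deliberately a different indexing
# scheme from the engine's
_WINDOW = (("P4", -4), ("P3", -3), ("P2", -2), ("P1", -1), ("P1'", 0), ("P2'", 1))


def naive_sites(sequence: str, spec: ProteaseSpec) -> list[int]:
    """Brute-force cut-site scan, independent of the digestion engine."""
    n = len(sequence)
    sites = []
    for bond in range(1, n):
        window = {
            label: (sequence[bond + off] if 0 <= bond + off < n else None)
            for label, off in _WINDOW
        }
        for pattern in spec.patterns:
            ok = True
            for pos, residues in pattern.constraints.items():
                if window[pos] is None or window[pos] not in residues:
                    ok = False
                    break
            if ok:
                sites.append(bond)
                break
    return sites


def naive_fragments(sequence: str, sites: Sequence[int]) -> list[str]:
    """Slice *sequence* at the given cut bonds."""
    cuts = [0, *sites, len(sequence)]
    return [sequence[a:b] for a, b in zip(cuts, cuts[1:])]


def gen_protein(
    seed: int | np.random.Generator,
    length: int,
    weights: Mapping[str, float] | None = None,
    protein_id: str = "SYN1",
) -> ProteinRecord:
    """Reproducible random protein of the given length and composition.

    ``weights`` maps one-letter codes to nonnegative weights (missing
    letters get 0); by default composition is uniform over the 20
    canonical residues.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if weights is None:
        probs = np.full(len(_ALPHABET), 1.0 / len(_ALPHABET))
    else:
        bad = set(weights) - CANONICAL_ALPHABET
        if bad:
            raise ValueError(f"weights for non-canonical residue(s) {sorted(bad)}")
        w = np.array([float(weights.get(ch, 0.0)) for ch in _ALPHABET])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative and sum to > 0")
        probs = w / w.sum()
    seq = "".join(rng.choice(_ALPHABET, size=length, p=probs))
    return ProteinRecord(id=protein_id, sequence=seq)


def _p1_only_sets(spec: ProteaseSpec) -> list[frozenset[str]]:
    return [
        p.constraints["P1"] for p in spec.patterns if set(p.constraints) == {"P1"}
    ]


@dataclass(frozen=True)
class PlantResult:
    """Outcome of planting one motif: the modified record and expectation."""

    record: ProteinRecord
    released: bool
    expected_fragments: tuple[str, ...]  # the motif itself, or its sub-fragments
    motif_start: int  # 0-based offset of the motif in the new sequence


def plant_motif(
    record: ProteinRecord,
    motif: str,
    spec: ProteaseSpec,
    position: int,
    anchor: str | None = None,
) -> PlantResult:
    """Insert ``anchor + motif`` at *position* so the boundaries are cleavable.

    The anchor residue is taken from a pattern of *spec* that
    constrains P1 only, making the bond before the motif a guaranteed
    cut site.  If the motif has an internal cut site, or its last
    residue is not itself a P1-only cut residue, the expected-release
    flag is False and the motif's own digestion fragments are recorded
    instead.  Raises :class:`PlacementError` when the rule set has no
    P1-only pattern to anchor with.
    """
    if not 0 <= position <= len(record.sequence):
        raise ValueError(f"position {position} outside sequence")
    if not set(motif) <= CANONICAL_ALPHABET or not motif:
        raise ValueError(f"motif {motif!r} is not a canonical peptide")
    p1_sets = _p1_only_sets(spec)
    if not p1_sets:
        raise PlacementError(
            f"{spec.name}: no P1-only pattern available to anchor a motif"
        )
    if anchor is None:
        anchor = min(p1_sets[0])
    elif not any(anchor in s for s in p1_sets):
        raise PlacementError(f"anchor {anchor!r} is not a P1-only cut residue")

    seq = record.sequence
    new_seq = seq[:position] + anchor + motif + seq[position:]
    new_record = ProteinRecord(record.id, new_seq, record.description)
    motif_start = position + 1

    internal = naive_sites(motif, spec)
    terminal_cleavable = any(motif[-1] in s for s in p1_sets)
    at_c_terminus = motif_start + len(motif) == len(new_seq)
    released = not internal and (terminal_cleavable or at_c_terminus)
    if released:
        expected = (motif,)
    else:
        expected = tuple(naive_fragments(motif, internal))
    return PlantResult(new_record, released, expected, motif_start)


@dataclass(frozen=True)
class PlantedMotif:
    protein_id: str
    enzyme: str
    motif: str
    released: bool


@dataclass(frozen=True)
class CellTruth:
    """Analytically expected digest outcome for one protein x enzyme."""

    sites: tuple[int, ...]
    fragments: tuple[str, ...]
    peptides: frozenset[str]
    matches: dict[str, frozenset[str]]   # matched peptide -> activities
    activity_counts: dict[str, int]      # full vocabulary, zeros included


@dataclass(frozen=True)
class SyntheticPanel:
    proteins: tuple[ProteinRecord, ...]
    enzymes: tuple[ProteaseSpec, ...]
    db: ActivityDB
    truth: dict[tuple[str, str], CellTruth]  # (protein_id, enzyme name) -> truth
    planted: tuple[PlantedMotif, ...]
    seed: int
    min_peptide_length: int = 2


def _sample_motif(rng: np.random.Generator, spec: ProteaseSpec) -> str:
    """A 3–8-mer guaranteed released by *spec* from any planted context."""
    p1_sets = _p1_only_sets(spec)
    terminal = sorted(set().union(*p1_sets))
    safe = sorted(CANONICAL_ALPHABET - spec.p1_union())
    length = int(rng.integers(3, 9))
    body = "".join(rng.choice(safe, size=length - 1))
    return body + str(rng.choice(terminal))


def _assign_activities(
    rng: np.random.Generator, index: int, vocabulary: Sequence[str]
) -> list[str]:
    acts = {vocabulary[index % len(vocabulary)]}
    for _ in range(int(rng.integers(0, 3))):  # up to 2 extras -> multifunctional
        acts.add(str(rng.choice(vocabulary)))
    return sorted(acts)


def gen_panel(
    seed: int,
    n_proteins: int = 16,
    n_motifs: int = 150,
    vocab_size: int = 12,
    n_decoys: int = 30,
    enzymes: Sequence[ProteaseSpec] | None = None,
    length_range: tuple[int, int] = (240, 420),
    min_peptide_length: int = 2,
) -> SyntheticPanel:
    """Build a full test panel with analytically known truth tables.

    Defaults mimic the shape of a small proteomic identification set
    digested by the three built-in plant proteases: 16 proteins x 3
    enzymes, 150 planted motifs, a 12-label activity vocabulary and 30
    decoy database entries.  Regenerating with the same seed and
    parameters reproduces the panel exactly.
    """
    if min(n_proteins, n_motifs, vocab_size, n_decoys) < 0 or n_proteins == 0:
        raise ValueError("panel dimensions must be positive")
    rng = np.random.default_rng(seed)
    if enzymes is None:
        enzymes = tuple(builtin_protease(n) for n in BUILTIN_NAMES)
    enzymes = tuple(enzymes)
    if vocab_size <= len(DEFAULT_ACTIVITY_LABELS):
        vocabulary = list(DEFAULT_ACTIVITY_LABELS[:vocab_size])
    else:
        extra = [f"activity-{i}" for i in range(vocab_size - len(DEFAULT_ACTIVITY_LABELS))]
        vocabulary = list(DEFAULT_ACTIVITY_LABELS) + extra

    # distribute plantings round-robin over protein x enzyme cells
    plant_plan: dict[int, list[ProteaseSpec]] = {i: [] for i in range(n_proteins)}
    for k in range(n_motifs):
        plant_plan[k % n_proteins].append(enzymes[(k // n_proteins) % len(enzymes)])

    proteins: list[ProteinRecord] = []
    planted: list[PlantedMotif] = []
    motif_activities: list[tuple[str, str]] = []  # (peptide, activity) pairs
    motif_index = 0
    for i in range(n_proteins):
        pid = f"SYNP{i + 1:02d}"
        specs = plant_plan[i]
        target_len = int(rng.integers(length_range[0], length_range[1] + 1))
        n_segments = len(specs) + 1
        seg_len = max(5, target_len // max(n_segments, 1))
        parts: list[str] = []
        for spec in specs:
            parts.append(gen_protein(rng, seg_len, protein_id="_seg").sequence)
            motif = _sample_motif(rng, spec)
            anchor = str(rng.choice(sorted(_p1_only_sets(spec)[0])))
            parts.append(anchor + motif)
            planted.append(PlantedMotif(pid, spec.name, motif, released=True))
            for act in _assign_activities(rng, motif_index, vocabulary):
                motif_activities.append((motif, act))
            motif_index += 1
        parts.append(gen_protein(rng, seg_len, protein_id="_seg").sequence)
        proteins.append(ProteinRecord(id=pid, sequence="".join(parts)))

    # expected peptide sets per cell, from the independent naive scanner
    cell_peps: dict[tuple[str, str], tuple[list[int], list[str]]] = {}
    all_expected: set[str] = set()
    for rec in proteins:
        for spec in enzymes:
            sites = naive_sites(rec.sequence, spec)
            frags = naive_fragments(rec.sequence, sites)
            cell_peps[(rec.id, spec.name)] = (sites, frags)
            all_expected.update(
                f for f in frags if len(f) >= min_peptide_length
            )

    # decoys: DB entries guaranteed absent from every expected peptide set
    motif_seqs = {m for m, _ in motif_activities}
    decoys: list[str] = []
    while len(decoys) < n_decoys:
        length = int(rng.integers(3, 9))
        cand = "".join(rng.choice(_ALPHABET, size=length))
        if cand in all_expected or cand in motif_seqs or cand in decoys:
            continue
        decoys.append(cand)
    pairs = list(motif_activities)
    for j, decoy in enumerate(decoys):
        for act in _assign_activities(rng, motif_index + j, vocabulary):
            pairs.append((decoy, act))
    db = build_activity_db(pairs)

    truth: dict[tuple[str, str], CellTruth] = {}
    for rec in proteins:
        for spec in enzymes:
            sites, frags = cell_peps[(rec.id, spec.name)]
            peptides = frozenset(
                f for f in frags if len(f) >= min_peptide_length
            )
            matches = {
                pep: db.entries[pep] for pep in sorted(peptides) if pep in db.entries
            }
            counts = {label: 0 for label in db.vocabulary}
            for acts in matches.values():
                for act in acts:
                    counts[act] += 1
            truth[(rec.id, spec.name)] = CellTruth(
                sites=tuple(sites),
                fragments=tuple(frags),
                peptides=peptides,
                matches=matches,
                activity_counts=counts,
            )

    return SyntheticPanel(
        proteins=tuple(proteins),
        enzymes=enzymes,
        db=db,
        truth=truth,
        planted=tuple(planted),
        seed=seed,
        min_peptide_length=min_peptide_length,
    )


def gen_score_table(
    seed: int,
    peptides: Sequence[str],
    n_above: int,
    threshold: float = 0.50,
) -> list[ScoreRecord]:
    """Score table with EXACTLY ``n_above`` scores >= threshold.

    Peptides must be unique.  One of the above-threshold scores sits
    exactly on the boundary, exercising the inclusive comparison.
    """
    peptides = list(peptides)
    if len(set(peptides)) != len(peptides):
        raise ValueError("peptides must be unique")
    if not 0 <= n_above <= len(peptides):
        raise ValueError("n_above outside [0, n]")
    rng = np.random.default_rng(seed)
    above_idx = set(rng.choice(len(peptides), size=n_above, replace=False).tolist())
    records = []
    boundary_used = False
    for i, pep in enumerate(peptides):
        if i in above_idx:
            if not boundary_used:
                score = threshold  # exact boundary case
                boundary_used = True
            else:
                score = float(threshold + (1.0 - threshold) * rng.random())
        else:
            score = float(threshold * rng.random() * 0.999)
        score = round(score, 6)
        if i in above_idx:
            score = max(score, threshold)  # rounding must not cross the boundary
        elif score >= threshold:
            score = threshold - 1e-6
        records.append(ScoreRecord(pep, score))
    return records
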