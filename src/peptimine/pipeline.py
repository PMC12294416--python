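"""End-to-end orchestration: digest -> match -> profile -> classify -> report.

A run is fully described by a :class:`PipelineConfig` (buildable from a
plain-text ``key = value`` file with an ``[enzymes]`` section); no
stage uses unseeded randomness, all tables are written with sorted,
stable ordering, and the run log carries no timestamps — so an
identical config produces byte-identical outputs.

All stages compute in memory first and files are written only at the
end, so a failing stage leaves no partial output behind.
"""

from __future__ import annotations

import configparser
import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from peptimine.activity import ActivityDB, load_activity_db, save_activity_db
from peptimine.digestion import DigestResult, digest
from peptimine.errors import PeptimineError
from peptimine.matching import (
    BioactiveMatch,
    build_activity_profile,
    build_heatmap_matrix,
    build_summary,
    heatmap_long,
    match_fragments,
)
from peptimine.rules import resolve_enzyme
from peptimine.scoring import (
    DEFAULT_THRESHOLD,
    classify_bioactive,
    load_scores,
    per_protein_bioactive_counts,
)
from peptimine.sequences import ProteinRecord, read_fasta, write_fasta
from peptimine.synth import SyntheticPanel

logger = logging.getLogger("peptimine")


@dataclass
class PipelineConfig:
    """Serializable settings for one reproducible run."""

    fasta: str
    db: str
    out: str
    enzymes: list[str] = field(default_factory=lambda: ["papain", "ficin", "bromelain"])
    min_peptide_length: int = 2
    counting: str = "distinct"          # or "occurrence"
    scores: str | None = None
    score_threshold: float = DEFAULT_THRESHOLD
    permissive: bool = False
    render_heatmap: bool = False
    seed: int | None = None             # only used by synth-mode helpers

    def __post_init__(self):
        if not self.enzymes:
            raise ValueError("enzyme list must be nonempty")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score threshold outside [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a plain-text config: ``[pipeline]`` keys + ``[enzymes]`` list."""
        parser = configparser.ConfigParser(allow_no_value=True)
        parser.read(path)
        sec = parser["pipeline"]
        enzymes = list(parser["enzymes"]) if parser.has_section("enzymes") else []
        kwargs: dict = {
            "fasta": sec.get("fasta"),
            "db": sec.get("db"),
            "out": sec.get("out"),
        }
        if enzymes:
            kwargs["enzymes"] = enzymes
        if "min_peptide_length" in sec:
            kwargs["min_peptide_length"] = sec.getint("min_peptide_length")
        if "counting" in sec:
            kwargs["counting"] = sec.get("counting")
        if "scores" in sec:
            kwargs["scores"] = sec.get("scores")
        if "score_threshold" in sec:
            kwargs["score_threshold"] = sec.getfloat("score_threshold")
        if "permissive" in sec:
            kwargs["permissive"] = sec.getboolean("permissive")
        if "render_heatmap" in sec:
            kwargs["render_heatmap"] = sec.getboolean("render_heatmap")
        if "seed" in sec:
            kwargs["seed"] = sec.getint("seed")
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = repr(sorted(asdict(self).items()))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PeptimineError):
                raise PeptimineError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, PeptimineError):
                raise PeptimineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow and write every report under ``config.out``.

    Outputs: per protein x enzyme digest TSVs and peptide FASTAs,
    ``matches.tsv``, ``summary.tsv``, ``activities_<enzyme>.tsv``,
    ``heatmap_long.tsv`` (plus an optional rendered ``heatmap.png``),
    an optional score-threshold table ``ranker_counts.tsv``, and a
    deterministic ``run_log.txt``.
    """
    with _stage("read_fasta"):
        proteins = read_fasta(config.fasta, permissive=config.permissive)
    with _stage("resolve_enzymes"):
        specs = [resolve_enzyme(tok) for tok in config.enzymes]
    with _stage("load_activity_db"):
        db = load_activity_db(config.db)

    with _stage("digest"):
        results: list[DigestResult] = [
            digest(rec, spec, config.min_peptide_length)
            for rec in proteins
            for spec in specs
        ]
    with _stage("match"):
        matches: list[BioactiveMatch] = []
        for res in results:
            matches.extend(match_fragments(res, db))
    with _stage("tabulate"):
        vocabulary = sorted(db.vocabulary)
        summary = build_summary(results, matches, counting=config.counting)
        profiles = {
            spec.name: build_activity_profile(matches, vocabulary, spec.name)
            for spec in specs
        }
        cells = [(rec.id, spec.name) for rec in proteins for spec in specs]
        wide = build_heatmap_matrix(matches, cells, vocabulary)
        long = heatmap_long(wide)

    score_table = None
    if config.scores:
        with _stage("classify"):
            records = load_scores(config.scores)
            bioactive, _ = classify_bioactive(records, config.score_threshold)
            provenance = {
                (r.protein_id, r.protease_name): r.peptides for r in results
            }
            score_table = per_protein_bioactive_counts(
                bioactive, provenance, all_scored=records
            )

    out = Path(config.out)
    with _stage("write"):
        (out / "digests").mkdir(parents=True, exist_ok=True)
        (out / "peptides").mkdir(parents=True, exist_ok=True)
        for res in results:
            stem = f"{res.protein_id}__{res.protease_name}"
            frag_df = pd.DataFrame(
                [
                    {
                        "protein_id": res.protein_id,
                        "enzyme": res.protease_name,
                        "start": f.start,
                        "end": f.end,
                        "sequence": f.sequence,
                    }
                    for f in res.fragments
                ],
                columns=["protein_id", "enzyme", "start", "end", "sequence"],
            )
            _write_tsv(frag_df, out / "digests" / f"{stem}.tsv")
            pep_records = [
                ProteinRecord(id=f"{stem}|{i + 1}", sequence=pep)
                for i, pep in enumerate(sorted(res.peptides))
            ]
            write_fasta(pep_records, out / "peptides" / f"{stem}.fasta")

        match_df = pd.DataFrame(
            [
                {
                    "protein_id": m.protein_id,
                    "enzyme": m.protease_name,
                    "peptide": m.peptide,
                    "activities": ";".join(sorted(m.activities)),
                }
                for m in matches
            ],
            columns=["protein_id", "enzyme", "peptide", "activities"],
        ).sort_values(["protein_id", "enzyme", "peptide"], kind="stable")
        _write_tsv(match_df, out / "matches.tsv")

        _write_tsv(summary.to_frame(), out / "summary.tsv")
        for spec in specs:
            prof = profiles[spec.name]
            rows = [{"activity": a, "count": c} for a, c in prof.counts.items()]
            rows.append({"activity": "Total peptides", "count": prof.bioactive_total})
            _write_tsv(pd.DataFrame(rows), out / f"activities_{spec.name}.tsv")

        _write_tsv(long, out / "heatmap_long.tsv")
        if config.render_heatmap:
            _render_heatmap(wide, out / "heatmap.png")

        if score_table is not None:
            _write_tsv(score_table, out / "ranker_counts.tsv")

        from importlib.metadata import version as _dist_version
        try:
            pkg_version = _dist_version("peptimine")
        except Exception:
            pkg_version = "unknown"
        log_lines = [
            f"peptimine {pkg_version}",
            f"config_hash {config.config_hash()}",
            f"seed {config.seed}",
            f"proteins {len(proteins)}",
            f"enzymes {','.join(s.name for s in specs)}",
            f"digests {len(results)}",
            f"sites {sum(len(r.sites) for r in results)}",
            f"fragments {sum(len(r.fragments) for r in results)}",
            f"matches {len(matches)}",
        ]
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def _render_heatmap(wide: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(
        figsize=(max(6, 0.4 * wide.shape[1]), max(4, 0.25 * wide.shape[0]))
    )
    labels = [f"{p} / {e}" for p, e in wide.index]
    sns.heatmap(wide.to_numpy(), ax=ax, cmap="viridis",
                xticklabels=list(wide.columns), yticklabels=labels)
    ax.set_xlabel("activity")
    ax.set_ylabel("protein / enzyme")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> Path:
    """Emit a synthetic panel as FASTA + DB TSV + truth tables (plain text)."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(panel.proteins, out / "proteins.fasta")
    save_activity_db(panel.db, out / "activities.tsv")
    truth = {
        f"{pid}|{enz}": {
            "sites": list(ct.sites),
            "n_fragments": len(ct.fragments),
            "peptides": sorted(ct.peptides),
            "matches": {p: sorted(a) for p, a in sorted(ct.matches.items())},
            "activity_counts": ct.activity_counts,
        }
        for (pid, enz), ct in sorted(panel.truth.items())
    }
    (out / "truth.json").write_text(json.dumps(
        {
            "seed": panel.seed,
            "min_peptide_length": panel.min_peptide_length,
            "enzymes": [s.name for s in panel.enzymes],
            "planted": [
                {"protein_id": m.protein_id, "enzyme": m.enzyme,
                 "motif": m.motif, "released": m.released}
                for m in panel.planted
            ],
            "cells": truth,
        },
        indent=1,
    ) + "\n")
    return out
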