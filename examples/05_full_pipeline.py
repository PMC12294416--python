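"""Run the whole pipeline from files, exactly as the CLI does.

Writes a synthetic panel to disk (FASTA + activity DB + score table),
executes digest -> match -> profile -> classify, and lists the report
files.  Rerunning the same config reproduces every file byte for byte.
"""

import tempfile
from pathlib import Path

import pandas as pd

from peptimine import PipelineConfig, run_pipeline
from peptimine.pipeline import write_panel
from peptimine.synth import gen_panel, gen_score_table

tmp = Path(tempfile.mkdtemp(prefix="peptimine_demo_"))
panel = gen_panel(seed=42, n_proteins=4, n_motifs=24, vocab_size=6, n_decoys=10)
write_panel(panel, tmp / "in")

peptides = sorted(set().union(*(ct.peptides for ct in panel.truth.values())))
scores = gen_score_table(seed=7, peptides=peptides, n_above=60)
pd.DataFrame([{"peptide": r.peptide, "score": r.score} for r in scores]).to_csv(
    tmp / "in" / "scores.tsv", sep="\t", index=False, lineterminator="\n")

cfg = PipelineConfig(
    fasta=str(tmp / "in" / "proteins.fasta"),
    db=str(tmp / "in" / "activities.tsv"),
    scores=str(tmp / "in" / "scores.tsv"),
    out=str(tmp / "out"),
)
run_pipeline(cfg)

print("reports written to", tmp / "out")
for p in sorted((tmp / "out").iterdir()):
    print("  ", p.name)
print("\nsummary.tsv tail:")
print(pd.read_csv(tmp / "out" / "summary.tsv", sep="\t").tail(4).to_string(index=False))
print("\nrun_log.txt:")
print((tmp / "out" / "run_log.txt").read_text())
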