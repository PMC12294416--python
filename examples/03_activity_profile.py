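"""Per-enzyme activity profiles and the protein x enzyme heatmap matrix.

A multifunctional peptide counts once per activity per protein, so the
per-activity column can sum above the distinct-peptide total.
"""

from peptimine import build_activity_profile, build_heatmap_matrix, digest, match_fragments
from peptimine.matching import heatmap_long
from peptimine.synth import gen_panel

panel = gen_panel(seed=42, n_proteins=4, n_motifs=24, vocab_size=6, n_decoys=10)
vocab = sorted(panel.db.vocabulary)

matches = []
for rec in panel.proteins:
    for spec in panel.enzymes:
        matches.extend(match_fragments(digest(rec, spec), panel.db))

for spec in panel.enzymes:
    prof = build_activity_profile(matches, vocab, spec.name)
    nonzero = {a: c for a, c in prof.counts.items() if c}
    print(f"{spec.name}: {prof.bioactive_total} bioactive (protein, peptide) pairs")
    for act, c in sorted(nonzero.items(), key=lambda kv: -kv[1]):
        print(f"   {act:<40s} {c}")

cells = [(r.id, s.name) for r in panel.proteins for s in panel.enzymes]
wide = build_heatmap_matrix(matches, cells, vocab)
print("\nheatmap matrix (rows = protein x enzyme, columns = activities):")
print(wide.to_string())
print("\nlong format head:")
print(heatmap_long(wide).head(6).to_string(index=False))
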