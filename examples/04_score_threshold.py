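"""Classify externally scored peptides at the 0.50 bioactivity threshold.

Scores come from a ranking tool as a peptide -> probability table; the
comparison is inclusive (score >= 0.50 is bioactive).  The generator
plants a known number of above-threshold scores so the classification
can be checked exactly.
"""

from peptimine import classify_bioactive, digest, per_protein_bioactive_counts
from peptimine.synth import gen_panel, gen_score_table

panel = gen_panel(seed=42, n_proteins=4, n_motifs=24, vocab_size=6, n_decoys=10)

peptides = sorted(set().union(*(ct.peptides for ct in panel.truth.values())))
records = gen_score_table(seed=7, peptides=peptides, n_above=60)

bioactive, inactive = classify_bioactive(records, threshold=0.50)
print(f"{len(records)} scored peptides -> {len(bioactive)} bioactive "
      f"(score >= 0.50), {len(inactive)} below threshold")

provenance = {
    (rec.id, spec.name): digest(rec, spec).peptides
    for rec in panel.proteins
    for spec in panel.enzymes
}
table = per_protein_bioactive_counts(bioactive, provenance, all_scored=records)
print("\nabove-threshold peptides per protein x enzyme (totals appended):")
print(table.to_string(index=False))
print("\nA peptide released by several digests counts in each of its cells.")
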