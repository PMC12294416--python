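"""Digest one protein with the three built-in plant proteases.

Complete hydrolysis cuts every bond matching the enzyme's specificity,
so the fragments are the maximal uncut substrings; "distinct peptides"
excludes single residues and repeated sequences.
"""

from peptimine import ProteinRecord, builtin_protease, digest

protein = ProteinRecord(
    id="DEMO1",
    sequence="MGKQSEDNRVAFLIPGGKYNEQWRGGTSPCVKHDEMRLLYAKPQTT",
)

for name in ("papain", "ficin", "bromelain"):
    spec = builtin_protease(name)
    res = digest(protein, spec, min_peptide_length=2)
    print(f"{name} (EC {spec.ec_number}): {len(res.sites)} cut sites, "
          f"{len(res.fragments)} fragments, {res.total_peptides} distinct peptides")
    print("  fragments:", " | ".join(f.sequence for f in res.fragments))

print("\nMore permissive specificity (bromelain cleaves after K, Y and any")
print("hydrophobic residue) means more cut sites and shorter peptides.")
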