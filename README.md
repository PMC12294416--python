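# peptimine

In silico protease digestion and bioactive-peptide mining for plant
protein hydrolysates.

## The problem

Food and nutraceutical researchers screen protein sources (e.g. the
cruciferin-rich meal left after rapeseed oil extraction) for peptides
with documented physiological activities — ACE inhibition
(antihypertensive), DPP-IV inhibition (antidiabetic), antioxidant
action and dozens more — before committing to wet-lab hydrolysis.  The
standard computational workflow is:

1. **digest** each protein with a chosen protease under the idealised
   assumption of *complete hydrolysis*: every peptide bond matching the
   enzyme's recognition motif is cleaved;
2. **search** the released fragments, by exact sequence, against a
   catalogue of known bioactive peptides;
3. **profile** the hydrolysate: how many distinct peptides, how many
   bioactive, which activities, per protein and per enzyme;
4. optionally **classify** the peptides with an external scoring tool,
   calling a peptide bioactive when its score ≥ 0.50 (inclusive).

`peptimine` implements this workflow as a reusable, fully testable
library with a thin CLI.  Enzyme specificities are written in
Schechter–Berger notation: for the bond between residues *i* and
*i*+1, P1 is residue *i* (cleavage is C-terminal to P1), P1′ is
residue *i*+1, P2 is residue *i*−1, and a rule such as
`P2:[AVLIFWY] P1:[KR]` constrains several positions at once.  Built-in
rule sets approximate the qualitative specificities of three plant
cysteine proteases:

| enzyme    | EC        | default rules |
|-----------|-----------|---------------|
| papain    | 3.4.22.2  | `P2:<hydrophobic> P1:[KR]`, `P1:<hydrophobic>` |
| ficin     | 3.4.22.3  | `P1:[R]`, `P1:[FY]` |
| bromelain | 3.4.22.32 | `P1:[KY]+<hydrophobic>` |

with `<hydrophobic>` = {A, V, L, I, F, W, Y, M}.  These are documented
approximations of qualitative literature statements; reproducing the
output of any particular online digestion service requires supplying
that service's own rules via a rule file (`--enzymes path/to/file`).

Because public peptide catalogues are versioned and licensed, the
package never bundles one: you point it at your own TSV export
(`peptide<TAB>activity<TAB>source_id`).  A synthetic-data module
generates proteins with bioactive motifs planted in cleavable
contexts, databases with decoy entries, and score tables with a known
number of above-threshold values — so the entire pipeline is testable
end to end with analytically known ground truth.

## Worked example

`examples/01_digest_protein.py` digests one 46-residue demo protein:

```
papain (EC 3.4.22.2): 18 cut sites, 19 fragments, 6 distinct peptides
ficin (EC 3.4.22.3): 6 cut sites, 7 fragments, 7 distinct peptides
  fragments: MGKQSEDNR | VAF | LIPGGKY | NEQWR | GGTSPCVKHDEMR | LLY | AKPQTT
bromelain (EC 3.4.22.32): 18 cut sites, 19 fragments, 8 distinct peptides
```

Ficin cuts only after R, F and Y, so it leaves long fragments; papain
and bromelain, with hydrophobic P1 preferences, fragment the chain far
more finely.  `examples/02_mine_bioactive_peptides.py` runs the full
mining step on a 4-protein synthetic panel and prints the summary
table (one row per protein × enzyme, grand totals appended):

```
protein_id    enzyme  total_peptides  bioactive_peptides
    SYNP01    papain              63                   4
    ...
  in total    papain             284                  13
  in total     ficin             165                   9
  in total bromelain             301                  16
```

`total_peptides` counts distinct released sequences of length ≥ 2;
`bioactive_peptides` counts those found verbatim in the activity
database.  The remaining examples build per-activity profiles and the
protein × enzyme heatmap matrix, apply the 0.50 score threshold, and
run the whole pipeline from files.

The same workflow is available from the shell:

```bash
peptimine synth --seed 42 --out panel/
peptimine run --fasta panel/proteins.fasta --db panel/activities.tsv \
              --scores panel/scores.tsv --out results/
```

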