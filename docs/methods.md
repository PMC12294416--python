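# Methods

## Digestion model

The engine simulates *ideal, complete hydrolysis*: for a protein of
length L, bonds are numbered 1..L−1 (bond *i* separates residues *i*
and *i*+1, residues numbered from 1), and every bond whose context
satisfies at least one cleavage pattern of the enzyme is cut
simultaneously.  Fragments are therefore the maximal uncut substrings;
no missed-cleavage enumeration, kinetic modelling (enzyme
concentration, time, pH, temperature) or sequential multi-enzyme
digestion is attempted, and only one enzyme acts per digest.  This is
the regime under which released fragments contain no internal
cleavage site, which the test suite verifies as a fixed-point
property (redigesting every fragment changes nothing).

A cleavage pattern is a conjunction of residue-set constraints over
the Schechter–Berger positions P4…P2′ (P1 mandatory; cleavage is
C-terminal to P1).  A constraint that refers to a position beyond
either terminus **fails** its pattern: no wildcard padding is
invented at the ends.  Consequences used by the tests: enlarging any
residue class is monotone (never un-matches a bond), a spec's
patterns behave as a union (adding patterns never removes sites), and
isolation of a fragment can only remove satisfied context constraints
— which is why complete hydrolysis is idempotent.

## Built-in enzyme rules

The papain/ficin/bromelain defaults encode qualitative specificity
statements from the protease literature (papain: hydrophobic motifs —
bulky hydrophobic P2 with basic P1, plus hydrophobic P1; ficin:
arginine at P1, plus aromatic P1; bromelain: cleavage adjacent to
lysine, tyrosine and hydrophobic residues).  The named class
`<hydrophobic>` is fixed as {A, V, L, I, F, W, Y, M} and redefinable
per call.  These rule sets are deliberately documented approximations:
online digestion services embed their own versioned specificity
matrices which they do not publish, so count-level agreement with any
particular service is not claimed; users who need it must supply that
service's rules as a rule file, which fully overrides the built-ins.

## Counting conventions

"Total peptides" per protein × enzyme counts **distinct** fragment
sequences of length ≥ 2 by default — free amino acids are not
peptides, and distinct-sequence counting is insensitive to repeated
identical fragments.  "Bioactive peptides" counts the distinct
released sequences found verbatim in the activity database; a
catalogue peptide buried inside a longer released fragment does not
count (encrypted-motif scanning is out of scope).  Both the length
floor (`min_peptide_length`) and the counting unit
(`counting=distinct|occurrence`) are configuration options because
catalogue tools differ on both.  Activity profiles count distinct
(protein, peptide) pairs per activity label, so a multifunctional
peptide contributes once per activity per protein and the per-activity
column may sum above the distinct-peptide total.  Output vocabulary
order is alphabetical for deterministic diffs.

## Ambiguity codes

Input sequences are uppercased and restricted to the 20 canonical
residues.  The codes B, J, O, U, X, Z are rejected by default with the
record id and position; with `permissive=True` they map to the
sentinel residue `X`, which can never satisfy a cleavage pattern
(patterns are restricted to canonical letters) and disqualifies any
containing fragment from database matching.  Silent guessing would
corrupt the count tables.

## Score thresholding

Scores are consumed from a file and never computed: the ranking model
behind them is an external, trained tool that is explicitly out of
scope.  Classification is inclusive (score ≥ threshold, default
0.50).  Unique sequences are scored once; the per-protein table joins
the classified set back to digest provenance, and a peptide released
in several digests counts in each of its cells.

## Synthetic data and what it does(n't) show

`gen_panel` builds the default test panel: 16 proteins × the 3
built-in enzymes, 150 planted motifs, a 12-label activity vocabulary,
30 decoy database entries, and protein scaffolds of 240–420 residues
(the scale of storage-protein subunits), uniform residue composition
unless weights are given.  Motifs are 3–8-mers — the typical bioactive
peptide length range — planted so that release under complete
hydrolysis is guaranteed by construction: every motif residue except
the last avoids the target enzyme's union of P1 sets (no internal
bond can be cut in any context), while the last residue and an
inserted anchor residue both come from a pattern of that enzyme that
constrains P1 only (both boundary bonds are cut in any context).

Ground truth (cut sites, fragments, peptide sets, matches, activity
counts per cell) is computed at generation time by a naive per-bond
scanner coded independently of the engine, so the end-to-end recovery
test is a genuine two-implementation cross-check rather than the
pipeline checking itself.  Decoy entries are resampled until absent
from every expected peptide set, making any decoy match a true false
positive.  Panels are byte-reproducible from (seed, parameters).

What passing these tests shows: the digestion semantics, matching,
counting and report plumbing are exact.  What it does not show:
anything about real proteomes — synthetic scaffolds have uniform
composition, no isoforms or signal peptides, no post-translational
modifications, and the planted motifs are cleavable by construction,
whereas real bioactive sequences are often flanked unfavourably.
Absolute peptide counts from synthetic panels are not comparable to
counts from curated catalogues.

## Numerical and design choices

* The FASTA given to the pipeline is treated as ground truth; no
  isoform or signal-peptide processing is applied.
* Score-table generation plants exactly *k* of *n* scores at or above
  the threshold and always includes one score exactly on the boundary,
  exercising the inclusive comparison; rounding is clamped so it can
  never move a score across the threshold.
* Pipeline runs are deterministic by design: no stage uses unseeded
  randomness, tables are written with stable sort order, LF endings
  and fixed float formatting, and the run log contains versions,
  a config hash and stage counts but no timestamps — identical configs
  give byte-identical outputs.
* All stages compute in memory before any file is written, so a
  failing stage (reported with its stage name) leaves no partial
  output.
* Verification problem sizes — 1000 random digestion instances of
  length 1–500 for the oracle comparison, the 16 × 3 panel, 500
  scored peptides — keep the whole suite and the acceptance script
  within a couple of seconds while covering every code path; the
  checks are exact (equality, zero violations), not statistical, so
  larger sizes would add runtime without adding stringency.

## Known limitations

* Exact-match mining only: substring/encrypted-motif search,
  similarity search and quantitative potency (IC50) fields are
  non-goals.
* No statistical comparison between enzymes is performed; the summary
  tables are deterministic counts from single simulated digests.
* Complete hydrolysis is an upper bound on fragment release; real
  digests are incomplete (steric hindrance, competition), so counts
  here are a qualitative inventory, not a quantitative prediction.
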