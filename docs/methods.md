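# Methods

## Scope and model

pspkit models the cooperative degradation of Gln/Pro-rich gliadin
peptides by an insect digestive peptidase complex, and the sequence- and
expression-level analyses used to characterise such a complex. The
chemistry is purely rule-based: each peptidase is a substrate-
specificity pattern, not a kinetic model. Reaction rates, enzyme
concentrations, pH gradients and time courses are out of scope; the
engine answers "can this bond be cut by this enzyme, and what is left at
the fixed point", not "how fast".

## Cleavage rules

A `CleavageRule` combines an action mode with residue-class constraints
on the positions around the scissile bond and substrate length bounds.
Residue classes mirror the Xaa/Xbb placeholders of peptidase general
formulas: `any` (Xaa), `non_pro` (Xbb), `pro`, `gln`. Bond `k` (1-based)
lies between residues `k` and `k+1`.

Decisions where the formulas left room:

* **CC (post-glutamine cathepsins).** Default mode cleaves every
  Gln↓Xbb bond on substrates of length ≥3, including bonds adjacent to
  a terminus; the Q↓P bond is never cut because proline bonds are the
  PSPs' territory. A `qq_only` mode restricts to Gln↓Gln. On gliadin
  repeats the modes typically coincide (nearly every Gln precedes Gln
  or Pro); the 26-mer worked example yields the identical site list
  [5, 10, 13, 18, 21] under both, which is tested.
* **POP flanks.** The (Xaa)₁₋₁₅ flanks are read as 1–15 residues
  strictly outside the Xbb-Pro↓Xbb core, so admissible substrates are
  5–33 residues and the scissile Pro is never within two residues of a
  terminus. A zero-length flank is not admitted; the alternative
  (flanks may be empty) would additionally allow POP to act as an
  exopeptidase, which contradicts its oligopeptidase character.
* **APP length.** Xbb↓Pro(Xaa)₁₋₉ is read as total substrate length
  3–11.
* **CND.** Treated as a dipeptidase cleaving any pair except Pro-Pro
  (an explicit `exclude_pairs` mechanism rather than a P1′ class),
  so Pro-X dipeptides — which no proline-specific enzyme touches — are
  cleared by CND while X-Pro remains primarily XPD's substrate.
* **PRCP.** The antepenultimate position is required non-Pro per the
  Xbb in its formula; whether real PRCP tolerates Pro there is
  uncertain, and the constraint is easily relaxed by editing the rule.
* **DPP 8** shares the DPP 4 rule (same S9B formula) under its own
  enzyme id so panels can include either or both.

## Digestion engine

An `EnzymePanel` is an ordered list of stages, each an ordered list of
enzyme ids with a compartment annotation (lumen/epithelium — annotation
only; it does not gate chemistry). Within a stage the engine repeatedly
fires the first applicable event under a fixed priority: enzyme listing
order, then fragment order (left to right in the current layout), then
lowest bond index. A stage ends when no enzyme applies to any fragment;
stages never revisit. Fragments of length 1 move immediately to the
free-residue pool and are not substrates.

This scheduling is a determinism contract, not a claim about in-vivo
concurrency. A shuffled-order probe over a 200-peptide synthetic suite
is part of the test suite: conservation must hold under any order, and
divergences of the final free-residue multiset are counted rather than
assumed absent (confluence is not asserted).

Two panels are packaged: `core` (CC → DPP4 + PRCP → XPD), the minimal
scheme that fully degrades the 26-mer γ-gliadin fragment to FLQP plus
free amino acids, and `extended` (adds POP to the luminal stage,
DPP 8/APP/LAP to the brush-border stage, CND to dipeptide clearance),
which also completes α-gliadin peptides whose N-terminal architecture
defeats the minimal panel.

Invariants: residue-multiset conservation for every digest; each event
increases the fragment count by one, so a length-n input terminates in
at most n−1 events.

## Classification

Anchor transfer uses pairwise global alignment (BLOSUM62, gap open 10,
extend 1, end gaps free) rather than multiple alignment: pairwise
against each reference is sufficient to read residues off reference-
numbered columns and is fully specified. Free end gaps make the
extraction invariant to terminal extensions or truncations of the
candidate, which is property-tested. Among co-optimal alignments the
aligner's first enumeration is used; anchor read-off only depends on
the alignment through the aligned-column map, so ties rarely matter in
practice.

Activity calls: `active` when all catalytic/metal/essential anchors
carry admissible residues (expected sets include synonymous
substitutions observed in active homologs, e.g. the DPP 4 S1 Trp
position admits W/L/F); `inactive_homolog` when exactly the
catalytic-Ser anchor deviates to a non-catalytic residue with the rest
intact (the DPP 10 pattern); `incomplete` otherwise, including any key
anchor falling in an alignment gap. S9B candidates get an exo-only vs
endo-capable annotation from the substrate-tunnel determinant position
(Asp/Asn vs Ala); S9A candidates are annotated with conserved-motif
counts (NGGSNGG, ADHDDRV, RAGHGAG).

The packaged anchor table uses human reference numbering keyed by
UniProt accession. Reference sequences are not redistributed; tests and
examples use synthetic references generated with the same anchor
structure (`gen_reference_profile`), which preserves every classifier
code path while keeping the repository free of external data.

## ORF clustering and consensus

Identity over an overlap comes from an ends-free pairwise alignment
(match +2, mismatch −2, gap open 5, extend 1, end gaps free). The
overlap is the set of columns where both sequences have residues;
identity's denominator spans from the first to the last such column and
by default counts internal gap columns (`count_gap_columns=False`
switches to the overlap columns only). For substitution-only tilings
the two conventions coincide. Clusters are the single-linkage closure
of pairs with identity ≥0.95 and overlap ≥10 residues; raising either
threshold can only refine a clustering, which is tested.

Consensus: members are laid out progressively in order of decreasing
length, each positioned by its ends-free alignment against the draft;
per column the majority residue wins, ties going to the longest
(earliest-placed) member, and singleton-coverage columns take their
sole member's residue. A member whose best alignment shares no overlap
with the draft is skipped with a diagnostic, yielding the consensus of
the largest consistent subset. ORF calling from nucleotide contigs is
out of scope; an optional length filter (`min_orf_length_filter`,
ORF ≥20% of the mRNA) is provided for completeness.

## Quantification

`contig_weight` implements the partial-alignment rule: a contribution
proportional to the aligned fraction when it exceeds half the contig's
length, zero at or below the cutoff (only the >50% branch is defined;
the zero branch is this package's reading of the rule's silence).
`count_units` gives each read exactly one unit: to its best-scoring
target under the default policy (ties broken lexicographically by
contig id) or split 1/k under the `fractional` policy — the "counted
once, not once per target" reading of multiread handling. `quantify`
scales each assigned unit by its alignment's contig weight, so in
tables without partial alignments RPKM recovery from the generator's
truth is exact, and with multireads whose best target is unique it
remains exact under the default policy.

Active-PSP percentages: 100 · RPKM / Σ(RPKM over active PSPs), where
the active set covers POP, DPP 4, DPP 8, PRCP, APP1–3 and XPD; DPP 10
(inactive homolog) and LAP/CND (post-proline cleavage is incidental to
their broad specificity) are excluded and carry no percentage.
Reported percentages round to 1 decimal, so a column of shares sums to
100 ± 0.3. The packaged fixtures carry both species' published RPKM
columns; the normalization reproduces every published percentage.

The midgut fractionation arithmetic (`fraction_percentages`) expresses
anterior/posterior activities as percentages of their sum, and each
section's four fractions as percentages of the section total; it is
arithmetic only, with no packaged activity data.

## Synthetic data

* **Gliadin-like peptides**: concatenated repeat motifs (default
  PQQPFPQ, PQQPFPQQ, PQPQPFP, PQQPY; two repeats) with 3–10-residue
  flanks per side drawn from non-Q/P residues. Composition caps
  (Gln ≤ 50%, Pro ≤ 35% of residues, per-peptide) emulate real gliadin
  composition; when a drawn flank leaves the peptide over a cap the
  flanks extend minimally until it holds, and a cap of zero for a
  residue present in the motifs raises. Real gliadins' higher-order
  repeat structure, rare non-standard residues and length distribution
  are not emulated — digestion tests on this generator exercise the
  rule engine's coverage of Q/P-rich sequence space, not gliadin
  biology.
* **ORF tilings**: windows every `step` residues over a uniform-random
  protein, plus a terminal window anchored at the C-terminus so
  coverage is complete; i.i.d. substitutions at `sub_rate` to a
  different uniform residue. Real ORF sets have indels, composition
  bias and uneven coverage; reconstruction results here bound only the
  substitution regime.
* **Read tables**: multinomial counts with probability ∝ weight ×
  length, realized truth RPKM returned (so recovery tests are exact,
  not asymptotic). Multireads gain one strictly lower-scoring secondary
  target; partial alignments draw an aligned fraction from
  U(0.55, 0.95), above the 50% cutoff. Mapping error, positional bias
  and fragment-length effects are not modelled.

All generators are pure functions of their specs, seed included.

## Numerical choices

* Masses: fixed average residue masses, water 18.02 Da, frozen as
  packaged constants so mass tests are byte-stable; additivity holds to
  1e-6 Da in floating point. Monoisotopic masses and modifications are
  out of scope.
* The 26-mer's computed average mass (3147.50 Da) agrees with
  Biopython's independent calculator to within the two libraries'
  water-constant difference (<0.01 Da).
* Problem sizes: property suites use 200 generated peptides; the
  at-scale digestion check uses 1,000 peptides under both panels;
  quantification recovery uses 20,000 reads over three genes; consensus
  accuracy uses a 300-mer at 3× interior coverage. These sizes make the
  full suite run in seconds while keeping every stochastic bound
  comfortably inside its tolerance at the packaged seeds.

## Known limitations

* No kinetics: the engine cannot reproduce hydrolysis time courses or
  fold-change activities; only endpoint fragment sets.
* The within-stage priority order is a convention; alternative orders
  can change intermediate fragments (endpoints on the worked examples
  are insensitive, which is tested, but this is not a theorem).
* Classification transfers anchors through pairwise alignment; highly
  diverged candidates (<~30% identity) may align ambiguously, and the
  activity call then degrades to `incomplete` rather than guessing.
* Consensus building assumes members tile a single locus; paralog
  mixtures that pass the identity threshold would be averaged, not
  separated.
* Table-level expression fixtures are reported values; the package
  does not re-map reads for the published columns, it reproduces the
  normalization arithmetic on them.
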