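# Methods

`venomminer` re-implements, as a reusable and fully tested library, a
combined transcriptome/proteome strategy for discovering disulfide-rich
venom peptides (the motivating system is sea anemone venom, whose peptide
toxins are classified into structural groups by their cysteine frameworks).
This note records the models, the parameters that matter, the numerical and
design choices, and what the synthetic studies do and do not demonstrate.

## The discovery model

A venom peptide precursor is modelled as `signal peptide + mature peptide`.
The mature peptide carries the *Cys framework*: the ordered pattern of
cysteines and inter-cysteine spacer lengths, written as a motif string
(e.g. `C8C3C11C5CC6`). Three search strategies feed one curation funnel:

1. **Contig-level homology** — pre-assembled contigs with a translated
   local-alignment hit against a broad protein database are six-frame
   translated into a predicted protein set.
2. **Read elimination** — raw reads with a translated hit against a pooled
   toxin database are assembled and translated.
3. **Group binning** — reads are binned per structural-group reference set,
   each bin is assembled independently, ORFs pass a four-rule precursor
   filter, and survivors are classified by framework.

Candidates from the three routes are merged on identical mature sequences
(the per-method overlap is reported as Venn regions), named by class
(`AnmTX` / toxin-like / polypeptide / venom protein), and validated against
tryptic-peptide evidence from the venom proteome.

## Cys-framework grammar

Motif strings are parsed by a small grammar: `C` a cysteine; an integer an
exact spacer; `[a-b]` a bounded spacer; `#` a spacer of unspecified length
(at least 1), so `##` is a gap of at least 2; adjacent `CC` a spacer of 0;
digits after the final `C` an exact trailing flank. Published strings mix
Cyrillic `С` with Latin `C` and decorate spacers with hyphens/en-dashes;
normalisation folds these away. Two readings of `##` were possible (two
open spacers summing to ≥ 2, or one spacer ≥ 2); they are arithmetically
identical under summation, and the chosen representation (two Open terms in
one gap) makes the printed motifs consistent with their stated mature
lengths (the symmetric 8-cysteine motif `C1C3C3C4C3C3C1C3` spans exactly 29
residues; `C8C3C11C5CC6` spans 39).

`span` counts cysteines plus explicit spacer/flank bounds; an *absent*
flank contributes nothing to span but is unconstrained in matching. A
framework extracted from a concrete peptide records residues before the
first cysteine in a separate `leading_offset`, because canonical motif
strings begin at the first cysteine; this keeps `format(parse(s))`
idempotent and `parse(format(fw)) == fw` exact.

Classification returns the unique matching registry entry; among several
matches the pattern with the fewest Range/Open terms (most specific) wins,
ties broken lexicographically; cysteine-free peptides are `linear`; no
match is `new` — novelty detection, not an error. The shipped registry
names the structural groups the motivating study encountered (1a, 1b, 1c,
3a, 6a, 8a, 10a, 11b, linear). Published sources do not enumerate spacer
patterns for all sixteen known groups, so the shipped spacer values are
package-defined exemplars chosen to be mutually exclusive (all-exact,
distinct gap vectors) and realistic in span (23–51 residues); the registry
is a plain `label<TAB>motif` text file and is user-extensible.

## Signal-peptide heuristic

Published pipelines use external signal-peptide predictors; to keep the
pipeline self-contained, deterministic, and testable, detection is a
transparent von Heijne-style rule set over the classical three-part
architecture: ≥ 1 K/R in the first 5 residues (n-region); an 8-residue
window within positions 3–20 with mean Kyte–Doolittle hydropathy ≥ 1.6
(h-region); and a (−3,−1) small-residue (A/G/S/T/C) cleavage site at a
position in [12, 40], at least two residues past the h-window, cleaving at
the smallest eligible position. All thresholds are explicit `SignalParams`
fields. The heuristic is calibrated to the synthetic generator's signal
architecture, not benchmarked against curated signal-peptide corpora —
results on real precursors will be noisier than the tests suggest.

## Homology search and E-values

Alignment is exact Smith–Waterman (BLOSUM62; affine gaps costing 11 + k
for a k-long gap) via Biopython's C aligner; reference sets are small
enough that no heuristic seeding is needed for correctness. Six-frame
translations are split at stops and segments ≥ 8 aa aligned independently.
Significance is Karlin–Altschul, `E = K·m·n·exp(−λ·score)` with the gapped
BLOSUM62-11/1 constants K = 0.041, λ = 0.267, computed against the
reference set's total residue count (the database convention).

Read binning accepts a read into every group with a hit at `E ≤ e_max`.
Two accelerations keep binning exact-in-spirit and fast: segments are
scored against the set's concatenated database (as database search tools
do; this can only over-admit, never drop a qualifying read), and an exact
4-mer prescreen skips set/read pairs sharing no seed — pairs whose best
alignments sit far below any practical threshold. The prescreen can be
disabled (`prescreen_k=None`) for exhaustive scoring.

**On the binning cutoff.** The nominal published threshold is E = 1.0.
With *calibrated* pair-level statistics, an E ≤ 1.0 cutoff admits ≈ 1−1/e
of purely random queries per search by construction — multiplied over six
frames and several segments, essentially every random read acquires some
hit at E ≤ 1.0 (we measured exactly that). Heuristic search tools report
far more conservative E-values for short translated queries, which is why
production pipelines of this kind bin only a few percent of their reads at
a nominal E = 1.0. The synthetic study therefore bins at `e_max = 1e-3`,
which reproduces that selectivity at desk scale; planted-homolog
alignments score ~10⁸-fold more significant than chance hits here, so the
choice is robust over many orders of magnitude. The library default for
the search operations remains the nominal 1.0.

## Assembly

A greedy overlap-layout-consensus assembler suits the post-binning scale
(tens to hundreds of reads per bin). Candidate placements are proposed by
shared 12-mers (both strands, containments included) and verified by exact
column comparison; the pair with the longest suffix–prefix overlap ≥
`min_overlap` (default 30 nt) at identity ≥ `min_identity` (default 0.95)
merges first; consensus is per-column majority over member reads, ties
resolved toward the longer fragment's base (and then by fixed base order).
Tie-breaks are canonical (overlap length, then lexicographically smallest
member read id), so output is invariant to input permutation, and member
bookkeeping guarantees no read is lost or duplicated. Qualities are
ignored after read-in. This is a deliberate, transparent stand-in for the
production assemblers used in the original study; it does not attempt
scaffolding, chimera detection, or isoform separation.

## Precursor filter and nomenclature

The four-rule filter keeps an ORF-derived precursor iff it is ≥ 50 aa,
contains no internal stop, has no long repeat, and carries a predicted
signal peptide. "Early termination" means a stop *inside* the precursor
span — the ORF's own terminating stop is legitimate. The repeat rule is
codified to cover both readings of "more than 5 amino acid repeats": a
single residue > 5 times consecutively, or a 2–5 residue unit tandemly
repeated > 5 times. Rejected candidates are retained with audit flags; the
first failing rule in order (length, stop, repeat, signal) is the primary
reason.

Nomenclature, applied in input order: precursors ≥ 200 aa are venom
proteins (`CjVP`); candidates with a named structural group *and* a toxin-
database hit at E ≤ 1e-3 are anemone neurotoxins (`AnmTX <tag> <group>-<k>`,
numbered within each group); otherwise matures < 60 aa are toxin-like
(`CjTL<k>`); the rest are polypeptides (`CjPP<k>`). The homology boundary
between the neurotoxin and toxin-like classes is not crisply defined in
the motivating study (published E-values straddle it), so the threshold is
a config field.

## Proteogenomic validation

Precursors are digested in silico with trypsin (cleavage after K/R except
before P; the WKP/MRP exception rules some tools add are deliberately
omitted), enumerating up to `max_missed` (default 1) missed cleavages.
Monoisotopic masses sum standard residue masses plus water (18.010565 Da),
with carbamidomethylation (+57.021464 Da per Cys) as the fixed
modification. Sequence-bearing observations match a predicted tryptic
peptide by exact equality (I/L treated as distinct — a documented
simplification); mass-only observations match within `tol_ppm` (default
10 ppm, TripleTOF-class accuracy). A precursor is validated when ≥ 2
distinct peptides match; coverage is the union of matched spans over the
precursor length. Spectrum modelling, FDR estimation, and protein
inference across shared peptides are all outside this evidence
abstraction.

## The synthetic study

The generator emulates the study design end to end, with defaults defining
the standard conditions: 20 planted toxin mRNAs cycling through the
registry's eight cysteine groups among 200 decoys (half shuffled-codon
coding ORFs, half non-coding), 250-nt reads at 20× expected coverage
(substitution-only errors at 0 or 1 %), per-group reference sets of 4
peptides realising each framework, planted matures derived from a
reference by 30 % non-Cys substitution (so binning has genuine homology to
find), 5′/3′ UTRs of 20–100 nt with an in-frame stop immediately before
the start codon (so the precursor ORF begins at its own Met), and 3
evidence peptides (length ≥ 6, masses within ±5 ppm) per planted protein.
Decoys are rejection-sampled so none passes the precursor filter with a
named framework. Signal h-regions cap homopolymer runs at 2 so the repeat
filter never fires on a planted precursor. All randomness flows from one
integer-seeded generator; fixed seed gives byte-identical output.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: indel-dominated single-molecule error
profiles (substitution-only keeps identity-based overlap detection
meaningful at desk scale), codon bias (immaterial to translated search),
expression-level variation, chimeric reads, isoforms/paralogs near the
assembler's identity threshold, and realistic spectrum-level noise.

## Problem sizes and verification

The standard study (20 planted + 200 decoys at 20×, ≈ 8–9 k reads) mines
in well under a minute per condition on one core; the test-suite and
acceptance-script sizes (200 alignment-oracle pairs at length ≤ 30, 1000
digestion-conservation proteins) were chosen so the whole suite stays
interactive. Measured on the standard study: error-free recovery and
correct classification of 20/20 planted toxins with base-perfect matures;
≥ 18/20 at 1 % substitutions; validation exactly equal to the ≥ 2-peptide
design; Smith–Waterman identical to a brute-force DP oracle on every
random pair; digest masses conserved to < 1e-6 Da. `scripts/acceptance.py`
recomputes all of these from scratch at an arbitrary seed.
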