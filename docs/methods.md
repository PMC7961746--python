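# Methods

## Scope and model of the data

`linearmito` analyses linear mitochondrial genomes as they come out of an
assembler: one nucleotide sequence per molecule (alphabet A/C/G/T/N,
uppercased, U mapped to T) plus an externally produced annotation set.
Coordinates are 1-based closed intervals (the GenBank convention), strands
are +1/−1 integers, and percentages are rounded half-up to two decimals,
the precision of published mitogenome tables. Gene prediction, circular
topologies and ambiguity codes beyond N are out of scope.

## Composition statistics

A+T content counts A and T over the full sequence length; N bases count
toward length but not toward A+T, so a sequence containing N can never
report 100%. The gene region is the length of the **union** of all
feature intervals — bases covered by two overlapping genes are counted
once. Published tables do not state whether they count overlapping bases
once or twice; union is the choice here, and comparisons against printed
gene-region values should keep that in mind. An overlap "case" is an
unordered pair of distinct features whose intervals intersect, across all
categories except pseudogenes, ignoring strand.

## Tandem repeat detection

The detector is **exact-match**: a call is a maximal region whose minimal
period equals the reported unit length, containing at least `min_copies`
(default 2) full copies, optionally ending in a partial copy that is a
proper prefix of the unit. Units are reported in genome phase (as first
observed at the leftmost position of the array) and reduced to the
primitive period (`ATAT×2` is reported as `AT×4`). Arrays strictly
contained inside a longer array are subsumed by it — an AT-rich 15-mer
array is one call, not a cloud of incidental `AT`/`ATA` sub-arrays.
Exactness makes every call reconstructible (`unit × copies + tail` equals
the substring) and lets the detector be verified against exhaustive
enumeration; the cost is that irregular repeat regions (some species carry
a short regular array plus an irregular remainder) are reported as the
regular core only.

**Telomeres** are tandem arrays anchored within 5 bp of each terminus,
searched inside a 500 bp window with unit lengths 6–60 bp (published
spirotrich units span 13–36 bp). The two terminal units are compared
rotation-aware: the call is symmetric when the reverse complement of the
3′ unit is a rotation of the 5′ unit, and the longest primitive unit
satisfying symmetry wins. Copy numbers are reported as observed in the
assembly; the biological copy number at the molecule ends is not knowable
from an assembly.

**TIRs** are found by exact 16-mer seeding between the 5′ window
(default 4 kb) and the reverse complement of the 3′ window, with ungapped
extension scored +1/−1 and an X-drop of 20; a call needs ≥100 bp at
≥90% identity. Approximate recovery is the goal — published TIR sizes are
themselves approximate ("~1800 bp"). Because the telomeric arrays of
these genomes are literally each other's reverse complements, the
composed classifier masks the telomere spans before the TIR search; a TIR
call therefore always means inverted sequence *beyond* the telomeres.
The standalone `find_tir` works on the raw sequence.

**Central repeat**: among interior tandem calls, the preferred evidence is
the highest-A+T call inside an intergenic interval flanked by *trnF* and
*trnY* (their conserved location). Without such an interval the fallback
takes the longest AT-rich call (≥80% A+T; published central repeats run
83–100%), breaking ties by distance to the genome midpoint, and flags the
loss of positional evidence. Length-first ordering matters: AT-rich
genomes are full of incidental dinucleotide arrays near any midpoint,
while real central repeats are 80–1600 bp.

**Divergent transcription** is quantified as the fraction of features
(excluding any overlapping the central interval) transcribed away from
it: strand −1 left of the center, +1 right of it. Fully divergent
architecture gives 1.0; strand-random annotation gives ≈0.5.

## Stem-loop models

Central repeats are folded by Nussinov-style dynamic programming
maximising Watson–Crick pairs (A·T, G·C) over nested structures with a
minimum hairpin loop of 3. The molecules are DNA, so no G·U wobble is
allowed, even though published secondary structures were produced with
RNA-oriented servers. Traceback is deterministic (pairing the interval
end is preferred over leaving it unpaired; the smallest partner wins
ties), so identical inputs give identical structures. A helix is a
maximal run of stacked pairs; `count_helices` keeps runs of ≥3 by
default. Maximum pairing is a declared surrogate for free-energy
folding: helix counts are qualitative shape descriptors, not
thermodynamic predictions, and are never compared against published
figures numerically. One known degeneracy: a tandem array of a
*perfectly* self-complementary unit folds into a single global hairpin
under pure pair maximisation (that is the optimum), whereas
quasi-palindromic units — including the published central-repeat units —
produce the multi-helix "sun-shape" whose helix count grows with copy
number.

## Synteny

Gene orders are signed label sequences taken from features sorted by
start, labels lower-cased; adjacent split-gene parts are fused into one
entry, non-adjacent parts stay separate (`_i`/`_ii`); duplicate labels are
matched across genomes by positional rank, surplus copies excluded from
block computation. The adjacency `(a, b)` is conserved when the other
order contains `(a, b)` or `(−b, −a)`; breakpoints are adjacencies of one
order absent from the other, making the count symmetric and zero for a
global flip of the whole molecule. Blocks are maximal runs of conserved
adjacencies; a block whose member strands are uniformly flipped in the
partner is tagged *inversion*, and a preserved-orientation block off the
longest order-conserved backbone is tagged *translocation*. This is a
qualitative, adjacency-based classification matching how organellar
comparisons are reported — not a minimal rearrangement-distance solver,
and a single biological event can in principle split into two tags; the
raw blocks are always included so users can re-interpret.

The tRNA cassette check (*trnQ–trnL–trnE–trnF–trnY–trnW*) requires the
present members to be consecutive **within the tRNA-only subsequence** of
the order (another tRNA interleaved breaks it; protein genes between them
do not) and in cassette order. The full reversal of the cassette is also
accepted, because an assembly may be reported on either strand; partial
scrambles (e.g. *trnY* before *trnF*) are rejected.

## Split-gene inference

Candidate ORFs are aligned to a full-length reference protein by
affine-gap alignment (BLOSUM62, gap open 11, extend 1) with free end gaps
on the reference, so a fragment aligns to its best reference substring.
Tie-breaking is deterministic (diagonal > gap-in-reference > gap-in-query).
Four criteria are then applied:

1. **Adjacent coverage** — two genomically adjacent ORFs cover disjoint
   N- and C-terminal reference spans, combined coverage ≥0.7, span
   overlap ≤30 aa.
2. **Length consistency** — each part within ±25% of the cohort mean for
   that part.
3. **TM similarity** — Kyte–Doolittle transmembrane-segment counts
   (window 19, threshold 1.6, minimum segment 15 aa, runs merged across
   gaps <3) within ±2 of the cohort mean per part.
4. **Split-site concordance** — the inferred split column (midpoint
   between the two covered spans) within ±30 aa of the cohort median.

Verdict `split` requires criterion 1 plus at least two of 2–4; a single
ORF covering ≥0.8 of the reference is `non_split`; criterion 1 without
enough support is `undetermined` — the signature of an apparent split
produced by an indel or sequencing error rather than a genuine gene
fission. No published numeric thresholds exist for "similar lengths" or
"almost identical sites"; the tolerances above are engineering choices
wide enough for the published spreads of part lengths, are exposed in the
API, and are reported with every verdict. The hydropathy profile is a
deliberately simple, deterministic stand-in for an HMM topology
predictor; helix counts are treated as cohort statistics, never as exact
targets.

## Synthetic genomes

The generator plants the full architecture with a recorded ground truth:
5′ telomeric array | optional TIR | gene arm on strand −1 | *trnQ–trnL–
trnE–trnF* | central repeat | *trnY–trnW* | gene arm on strand +1 |
optional inverted TIR | 3′ array (reverse complement of the 5′ array).
Defaults are study-scale: 50 kb, A+T bias 0.77, 45 genes of 300–1500 bp
(plus rRNAs of 2500/1500 bp and 72 bp tRNAs), a 31 bp telomere unit × 4
copies, an AT-palindromic 16-mer central unit × 11 copies with a 5 bp
tail, seven planted overlap events of 4–100 bp, *nad1*/*nad2*/*rps3*
split at their midpoints, no TIR and no mutations. Telomere copy number
4 reflects assembly-scale arrays (the biological number is unknown);
coding proportion lands near ~85%, slightly below the densest real
genomes, because gene bodies are drawn independently of the spacer
budget. Tests that need speed pass smaller `genome_len`/`n_genes`
explicitly.

Random central units are built `w + revcomp(w)` over {A,T} and re-drawn
until primitive, guaranteeing foldability and a well-defined unit.
Guard bases adjacent to every planted array are forced to break the
tandem period, so planted spans are recovered *exactly* rather than
modulo chance extensions. Point mutations (optional) avoid the planted
repeat spans by default; noise tests disable the mask deliberately.
Cohorts share one architectural plan and draw per-genome sequence from a
`(seed, index)` stream, so members are independently reproducible; planted
edits (deletion, duplication, inversion, translocation, telomere
replacement) are applied to the plan and recorded in each manifest.

What the generator does **not** emulate: codon structure, sequencing
error profiles, assembly artefacts, irregular partial repeats, and
length heterogeneity of real gene families. Passing recovery tests on
synthetic cohorts therefore demonstrates correctness of the detectors'
contracts, not robustness to every property of real assemblies.

## Numerical and degenerate-input choices

Empty sequences, empty ORF lists, and coordinate violations raise
`ValueError`/`ParseError` naming the offender. The folder accepts any
sequence of ≥2 bases (shorter than `min_loop + 2` simply folds to zero
pairs). Fewer than two shared genes yields an empty synteny report with
a warning flag rather than an error. All detector tolerances (windows,
unit-length bounds, anchor tolerance, AT-rich threshold, identity
threshold, split-gene tolerances) are keyword arguments with the defaults
stated above.

## Problem sizes used in the checks

The bundled verification suite runs the tandem detector against
exhaustive enumeration on sequences ≤60 bp, the folder against a
brute-force recursion on sequences ≤12 nt, breakpoint counts against
adjacency-set comparison on signed permutations of ≤15 genes, and the
aligner against exhaustive path enumeration on peptides ≤6 aa (the
enumeration grows as the Delannoy numbers) plus an independently
configured library aligner on peptides ≤12 aa. Parameter recovery runs
on 20–40 seeded genomes of 20–22 kb with 14–18 genes, and split-gene
recovery on 400 aa references; these sizes exercise every code path at
desk scale.
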