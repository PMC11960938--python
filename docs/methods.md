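# Methods

## Alignment engine and the PID3 statistic

Segment homology is measured with a three-state affine-gap
Needleman–Wunsch dynamic program written from first principles (numba-jit
inner loops, full traceback). Scoring follows the EDNAFULL/NUC.4.4 matrix
(match +5, mismatch −4, ambiguity-aware; the numeric table is loaded from
Biopython's `substitution_matrices`), with a deliberately harsh gap model:
a gap run of length L costs `gap_open + gap_extend × L` with
`gap_open = 25`, `gap_extend = 10`. End gaps are free on both sequences
("overlap" mode), so a shorter segment may sit anywhere inside a longer
one at no cost. The identity summary is

    PID3 = 100 × (identical aligned positions) / (length of the shorter input)

Two consequences matter for interpretation. First, because gaps are
expensive, alignments are driven to contiguous blocks of true homology;
diverged inputs are *trimmed* rather than force-aligned, so PID3 of
unrelated or saturated pairs collapses toward a few percent instead of
hovering at the ~25% random-identity baseline. Second, PID3 of two equal
ambiguity letters counts as identical; an ambiguity letter never matches a
different letter. Inputs are uppercased on ingestion; soft-masking is
ignored.

Numerical choices: traceback ties prefer diagonal over up (gap in the
second sequence) over left; with free end gaps the alignment end cell is
the maximum over the last row/column, ties resolved toward the full-length
corner in a fixed scan order. The DP is exact O(nm) without banding —
segments here are ≤ ~10 kb.

Correctness is anchored two ways: an exhaustive oracle that enumerates
every alignment as a monotone move string and scores it under the same
cost model (equality on random pairs up to length 7, both end-gap modes),
and an independent cross-check against Biopython's `PairwiseAligner`
configured to the same scheme.

## Loci, segments and orientation

Family genes (those with ≥1 catalytic A/PL7 domain) are clustered per
contig by single linkage at `max_gap` (default 20 kb; the published loci
were curated by hand, and the 10-kb unlinked-locus scale below argues
tandem arrays are tighter than 20 kb, so the parameter is exposed rather
than asserted). Loci are numbered by contig size descending, then
position. Each locus is segmented LF, G1, IGR1, …, Gn, RF with 2.5-kb
flanks truncated at contig ends; segments tile the extended span exactly,
and zero-length IGRs are legal for abutting genes. Intergenic sequence is
always taken from the forward strand; a reverse-complement comparison is
not needed for co-oriented tandem arrays and is therefore not applied by
default. Coordinates are 0-based half-open internally; GFF3 (1-based,
inclusive) is converted at the boundary.

Orientation of a tandem locus is *unidirectional head-to-tail* iff all
family members share a strand; an intervening-gene flag records whether
any non-family gene lies inside the locus span.

Telomeric ends: a contig end is telomeric iff ≥3 tandem copies of
TTAGGG (either strand) occur within 500 bp of the end. Tandemness and the
window keep chance hexamers out; the published census (one contig with
both ends, 22 with one end) then gives ⌈24/2⌉ = 12 chromosomes minimum.

## Recency calling

Unequal crossing over duplicates a gene together with its downstream
intergenic region, so a fresh junction has two identical consecutive
IGRs. "High homology" is made operational with two thresholds applied to
each consecutive IGR pair:

* an empirical null — PID3 of one IGR against `n_shuffles = 100`
  mononucleotide shuffles of the other; the observation must exceed the
  1−α quantile (α = 0.05);
* an absolute floor (50%), because overlap alignment of short sequences
  can produce occasional inflated PID3 values, and because a pair that
  beats a ~3% null at, say, 20% identity is detectable homology but not a
  *recent* duplication.

IGRs shorter than 30 bp are reported as not assessable rather than
aligned. All shuffle seeds derive from one caller seed, so calls are
deterministic.

## The drift clock in the simulator

Intergenic decay is modelled as Jukes–Cantor substitution: per-site
substitution probability `p = ¾(1 − exp(−4μt/3))` with μ = 1 per unit
drift time, substitutions uniform over the three alternatives, indels off
by default. Coding sequence is held fixed during drift, standing in for
purifying selection on the genes. **Convention:** a junction "at drift t"
means each IGR copy evolves independently for time t after the
duplication, i.e. pairwise divergence 2t. At t = 0.02 a junction retains
~96% identity; at t = 0.8 (divergence 1.6) the alignment finds almost no
contiguous homology and PID3 falls to a few percent, below the floor —
this separation is what the recency benchmark (25 + 25 simulated loci,
800-bp IGRs) quantifies as sensitivity and specificity.

## Transposition inference

Loci are *unlinked* when on different contigs or separated by more than
10 kb on the same contig. On a bootstrap-labelled A-domain tree, maximal
clades with support ≥ 100 whose leaves span ≥2 pairwise-unlinked loci and
contain ≥ `min_locus_coverage` (default 0.5 — "most genes" made explicit)
of each involved locus's domains are reported as transposition events;
nested qualifying clades collapse into the maximal one. Supports are
treated as bipartition properties (remembered by leaf set and
complement), which makes inference invariant to rerooting; unrooted input
trees are midpoint-rooted first. The simulator emits rooted trees, as a
midpoint-rooted input tree would be, with one planted 100-support
cross-locus clade and one decoy at support 80 per tree.

The companion subsampling scheme for building a reference phylogeny from
a large similarity search bins hits by bit score from the minimum score in
intervals of 50 (10 bins, overflow into the last), draws 25 per bin
uniformly without replacement, then applies a description filter and a
one-per-species dedupe (highest score kept). Bin anchoring at the minimum
score is the simplest scheme consistent with fixed-width bins.

## Family classification and protein audits

Domain hits come from hmmscan `--domtblout` (parsed via Biopython
SearchIO) or an equivalent TSV, filtered at i-evalue ≤ 1e−3 (1e−10 for
CAZyme assignment). Overlapping hits are resolved by keeping the lower
i-evalue and dropping hits that overlap a kept hit by >50% of the shorter
— hmmscan emits nested hits and some rule is required. Signal peptides
and TMDs are ingested as annotations, not predicted.

Rules, applied in order to genes with ≥1 A domain: (1) C-terminal TMD
(any TMD at/after the last A) and no C → `AnTMD`; (2) ≥2 A and ≥1 C →
`AnCn`; (3) otherwise `CA`, with subfamily `CCA` when the architecture
contains C-C-A and `A_only` when C was lost. The rules are total and
mutually exclusive (property-tested over random architectures).

Catalytic-motif audit: regular expressions `R.E[LV]R`, `Q[IV]H`,
`YFK.G.Y.Q` over the A-domain protein; a domain is intact iff all three
match. The simulator plants concrete motif instances at fixed offsets and
scrubs accidental matches elsewhere, so knockouts are exactly attributable.
Insertion detection aligns an A-domain CDS to a reference with end gaps
penalised and reports the longest internal gap opened in the reference;
an insertion is called at length ≥15 and divisible by 3 (in-frame).
TARP repeats are counted as non-overlapping `T[APSV]RP` matches, scanning
N→C.

## CAZyme profiles

Per-species family counts are normalised to percentages of the species
total (zero-count species are an error), compared with Bray–Curtis
dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) and ordered by average-linkage (UPGMA)
agglomeration — the conventional partner of Bray–Curtis profile heatmaps;
the linkage is configurable since the original choice is unstated. Both
implementations are backed by scipy with hand-arithmetic oracles in tests.

## What the simulator does and does not emulate

It reproduces the *mechanistic* signal each inference consumes: head-to-
tail duplication with shared spacers, locus dispersal beyond the 10-kb
unlinked threshold, domain gain/loss/duplication, in-frame insertions,
motif knockouts, telomere runs, and JC decay of intergenic DNA. It does
not emulate repeats/transposable elements, indel mutation, codon-level
selection, assembly error, or annotation noise — so passing benchmarks
demonstrate correctness of the inference machinery under the stated model,
not robustness to every artefact of real assemblies. Problem sizes used
throughout (800-bp IGRs, 3-gene loci, 50-locus benchmarks, 20 trees,
L = 10,000 drift calibrations) were chosen as the smallest at which the
relevant signals are unambiguous on a single CPU.

## Known limitations

* Locus calling with any fixed `max_gap` may merge or split relative to a
  hand-curated locus set; the parameter is exposed for that reason.
* The recency floor (50%) is a calibration choice, not an estimate of the
  authors' visual threshold; published per-locus recency lists are treated
  as qualitative context only.
* Transposition inference reports per-locus coverage so both readings of
  "most genes form a clade" (strict vs loose) can be audited after the
  fact.
* PID3's shorter-length denominator means a short segment fully contained
  in a long one scores 100; this is intended (free end gaps) but makes
  cross-length comparisons asymmetric in information content.
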