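# Methods

## Scope and data model

`ribostall` analyzes bacterial ribosome-profiling libraries at the level of
individual CDSs: each gene is treated as an independent transcript, reads
never span gene boundaries, and all coordinates are 0-based half-open
internally (SAM I/O converts to 1-based at the boundary). Amino-acid
sequences retain the terminal `*` so codon indices map one-to-one onto
nucleotide codons, including the stop; reads whose A site falls in the stop
codon are retained at the stop-codon index.

## Read preprocessing

Raw reads follow the layout `QQQ — fragment — UMI(5) — barcode(5) —
adapter`. Decomposition removes the three untemplated 5′ bases, locates the
adapter by exact match (a trailing partial adapter — the longest adapter
prefix terminating the read — is also trimmed), discards reads without an
adapter (`NO_ADAPTER`) or shorter than 30 nt after trimming (`TOO_SHORT`;
the bound applies to fragment+UMI+barcode, so fragments are ≥ 20 nt), and
splits the remainder from the 3′ end. Adapter matching is exact by design:
the pipeline targets error-free synthetic reads, and the error-tolerant
semantics of production trimmers is documented rather than emulated.
Deduplication keeps the first occurrence of each (UMI, fragment) pair;
including the fragment in the key avoids collapsing distinct molecules that
happen to share one of the 4^5 = 1024 UMIs. Libraries are assumed
demultiplexed, so the barcode is carried but not used.

## Mapping and A-site assignment

Fragments are first removed if they occur as an exact substring of any
contaminant (rRNA/tRNA) sequence on either strand. Mapping is exact-match
and unique-hit over the transcriptome (both strands, via
reverse-complement search on a separator-joined index): one occurrence
yields an alignment, more than one is discarded as multi-mapped, zero as
unmapped. This is a deliberate stand-in for mismatch-tolerant short-read
alignment — the package's scope is the post-alignment analysis, and a SAM
reader accepts externally produced alignments as an alternative input.
Self-reverse-complementary fragments count one locus, not two.

The A site sits a fixed offset (default 11 nt, configurable — the offset is
library-specific and should be re-estimated for real data) upstream of the
footprint's 3′-terminal base, measured along the read's 5′→3′ direction;
minus-strand alignments mirror the orientation. The codon index is
`floor((asite_nt − cds_start)/3)`; A sites outside the CDS are excluded and
logged. Per-gene profiles count A sites at nucleotide resolution; codon
counts are the 3-nt sums. Replicate aggregation is an element-wise sum
(commutative and associative), matching the practice of pooling all
replicate alignments per strain before pause prediction.

## Pause scoring

The score at nucleotide *i* is the mean over two window sizes *w₁*, *w₂*
(defaults both 1000 nt) of `count[i] / mean(window)`, where each window is
centered at *i* (positions *i−⌊w/2⌋ … i+⌊w/2⌋*), clipped at the gene ends,
and excludes *i* itself so a tall spike does not dilute its own
denominator. The score is undefined (site skipped and logged) when a
window's mean is zero. Coverage is the fraction of non-focal positions
with ≥ 1 count in the larger clipped window. A site is reported when
score ≥ 20 and coverage ≥ 5% — the fold-change and coverage semantics of
sliding-window pause predictors, pinned here by an independent brute-force
oracle in the test suite. Whether the two windows should instead be
upstream/downstream flanks is ambiguous in the source material; the
centered reading is adopted and fully specified. Adjacent super-threshold
nucleotides are reported individually (no merging). The score is invariant
under scaling a profile by any k > 0 and monotone in the focal count.

## Motif statistics

The trimer under a paused ribosome is the E-, P- and A-site residue triple
`aa[c−2], aa[c−1], aa[c]` for A-site codon *c*; undefined within two codons
of the start or when it contains a stop. Each reported pause site counts
once (unweighted). The background frequency of a trimer is
occupancy-weighted — Σ codon counts at positions carrying that trimer over
Σ counts at all defined-trimer positions — i.e. the trimer's frequency in
what ribosomes actually covered, not in the transcript sequence.
Enrichment is the ratio; a trimer at pause sites with zero background is
flagged rather than given a finite ratio. E-site codon bias is the
per-position nucleotide frequency matrix of the codon at *c−2* over pause
sites, with the first-position guanosine fraction reported separately.

The asymmetry score is `AS = (Σ downstream + α)/(Σ upstream + α)` over
*F* = 25 codons on each side of the motif span (span excluded, flanks
clipped at the CDS but required to keep ≥ 5 codons, pseudocount α = 0.5).
Flank size, α and the dependency threshold θ are parameters, not constants:
the source analyses do not fix them, and all package defaults are stated
here and in the function signatures. Dependency of a gene on a rescue
factor compares mutant vs wild-type scores at θ (default 2): DEPENDENT when
`AS_mut ≤ AS_wt/θ`, INDUCED when `AS_mut ≥ AS_wt·θ`, INDEPENDENT otherwise.

## The footprint simulator

The simulator defines the conditions under which the pipeline is
validated. Transcriptomes are uniform-random sense codons with an ATG
start, a terminal stop and no internal stops; planted stall trimers occupy
codons *c−2…c* with synonymous codons drawn at random (optionally
constrained to a first nucleotide for the E-site codon — note the genetic
code makes G-starting fully determined by the amino acid, so mixtures of
trimers, not codon sampling, set a fractional G rate).

Dwell is multiplicative and memoryless: weight 1 per codon, multiplied by
*s* at a planted A-site codon, and by (1 − d) at every codon downstream of
a drop-off motif — the simplest model whose fold-change and asymmetry
semantics match the statistics being tested. A-site codons are drawn
multinomially with probability ∝ dwell; the read count per gene is
depth × (number of feasible codons). The true A-site nucleotide is the
first nucleotide of the codon; the 3′ end is placed exactly `offset` nt
downstream, the read length drawn uniformly on 20–40 nt (clipped near the
5′ end; codons whose footprint cannot fit get zero weight — in practice the
first three and last few codons). The 20–40 nt range reflects a gel-cut
size selection; the uniform length distribution is an assumption, as no
empirical length profile is modeled. Raw reads are assembled with 3 random
untemplated bases, a random 5-nt UMI, a fixed per-sample barcode, the full
adapter, and constant `'I'` qualities (the pipeline never uses qualities).
PCR duplicates are injected per read with probability `dup_rate`, copying
fragment and UMI. A per-read truth table (true A site, UMI, duplicate-of)
makes every downstream stage exactly checkable. Identical configs and
seeds give byte-identical output.

What the simulator deliberately omits — sequencing errors, MNase sequence
bias, rRNA contamination, footprint-length structure, ribosome queuing
upstream of stalls, initiation/termination dynamics — bounds what passing
tests show: they validate the arithmetic and bookkeeping of the pipeline on
data satisfying the model's assumptions, not robustness to the noise
sources of real libraries.

A note on dependency recovery under the default validation conditions:
with drop-off modeled as a single (1 − d) downstream scale, the mutant
asymmetry converges to AS ≈ 1 − d while the wild type sits at 1, so a
drop-off of d produces at most a 1/(1 − d)-fold score change. At d = 0.3
that is ≈ 1.43-fold — below a θ = 2 dependency threshold — so detecting
such stalls requires either θ ≤ 1/(1 − d) or stronger drop-off; the
acceptance suite records this arithmetic honestly rather than tuning
around it.

## The loop classifier

The β3Ωβ4 loop region is located by finding the reference loop sequence
(e.g. *E. coli* EF-P `KPGKGQA`) exactly once in the ungapped reference row
and taking the minimal alignment-column interval spelling it; each
sequence's loop is its non-gap residues within those columns, which makes
extraction invariant to gap-column insertion. The tip is operationalized as
the middle residue ⌈L/2⌉ — this reproduces the canonical anchors (K at
position 4 of `KPGKGQA`, R at position 5 of `SPTARGAAT`); the classifier is
a pure function of the loop: EFPL iff length > 7 with an R tip, EFP for
1–7 residues, OTHER otherwise. Building the MSA, phylogenetic inference
and domain scanning are out of scope — inputs are assumed to be aligned
KOW-domain sequences.

## Validation problem sizes

Unit and property tests run on genes of tens to hundreds of codons with a
few thousand reads. The end-to-end reference scenario uses 20 genes × 300
codons at depth 50 (≈ 3.5 × 10⁵ raw reads per pair of libraries, ≈ 1 min on
one CPU) — large enough that sampling error sits well inside the asserted
tolerances (per-codon counts ≈ Poisson(50); a planted multiplier of 50
yields fold changes two orders of magnitude above background), while
remaining a desk-scale computation. Oracle-equivalence tests compare
against direct-loop reimplementations at 1e−9 on ≥ 100 random instances
per operation.
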