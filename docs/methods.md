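# Methods

## Scope and model

`tadloops` implements a genome-wide chromatin-architecture analysis around
two linked observations in erythroid cells: (i) a minority of p300 binding
sites carry no H3K27ac — candidate non-classical regulatory elements — and a
small fraction of chromatin loops and TAD-boundary interactions connect such
a "p300-only" site on one anchor to an H3K27me3 (Polycomb) mark on the
other, forming a repressive loop that lowers expression of the H3K27me3
promoter gene; and (ii) some TADs are anchored by two same-strand genes in a
head-to-tail conformation (the upstream gene's 3' end at one boundary, the
downstream gene's promoter at the other), in which the downstream gene
restrains the upstream one.

All coordinates are 0-based half-open (BED convention); overlap means at
least one shared base pair, so abutting intervals do not overlap — matching
bedtools/pybedtools defaults.

## Feature windows and classification rules

| window | definition | default |
|---|---|---|
| promoter | transcript 5' edge +/- flank | 1 kb |
| terminator | transcript 3' edge +/- flank | 5 kb |
| TAD boundary | domain start/end +/- flank | 5 kb |
| H3K27ac extension | peak +/- flank before the p300 anti-intersection | 1 kb |
| signal profile | peak midpoint +/- flank, fixed-width bins | 5 kb / 50 bp |

Windows are centered on the transcript *edge coordinate* (tx_start for a
plus-strand promoter, tx_end for a minus-strand one), keeping them symmetric
in the half-open system; the single-base TSS/TES positions reported on the
gene model follow the usual convention (TSS = tx_start on +, tx_end − 1
on −).

**p300-only peaks** are whole p300 peaks with zero overlap against the
H3K27ac set extended by +/-1 kb; peaks are never truncated.

**Peak feature annotation** assigns exactly one label per peak, decided at
the peak midpoint with precedence promoter > 5'UTR > 3'UTR > exon > intron >
downstream > intergenic (the one-label-per-peak behaviour of ChIPseeker-style
annotators). Introns are numbered in transcription order, so intron 1 of a
minus-strand gene is its highest-coordinate intron. UTR labels require CDS
bounds (BED12 thickStart/thickEnd); without them UTR positions report as
plain exon. Because the promoter window outranks everything, positions
within 1 kb of the TSS always label as promoter even when they fall inside
intron 1; the intron walk is therefore exercised with a tight promoter flank
in the tests.

**Anchor annotation** uses precedence promoter > terminator > gene body >
intergenic over all genes intersecting the anchor, plus independent boolean
flags for p300-only and H3K27me3 overlap. In the pair category label the
mark flags outrank the gene feature (an anchor with a p300-only peak
displays as `p300only` regardless of gene context), since the censuses list
the marks as top-level categories alongside Promoter/Terminator/Genebody.

**Mark fraction.** A loop or boundary pair is "anchored by p300-only and
H3K27me3" when the two marks sit on *opposite* anchors; a same-anchor
co-occurrence mode exists behind a flag but is off by default, matching the
promoter-H3K27me3 <-> intronic-p300 geometry the repressive loop describes.

**Head-to-tail detection** emits one record per (TAD, upstream gene,
downstream gene) with: same strand; upstream precedes downstream in
transcription direction; the upstream terminator window overlaps one
boundary window and the downstream promoter window overlaps the partner
window of the same TAD. The 3' overlap is operationalized as the terminator
window; an optional gene-body fallback widens it. Isoforms sharing a gene id
are tested independently and deduplicated by id. Detection is invariant
under whole-genome reflection plus strand flip (tested).

**Expression comparisons** are on the log2(TPM+1) scale. The two-group
comparison takes genes whose promoter window intersects the partner anchor
of a p300-only-marked loop anchor, split by promoter H3K27me3 overlap (the
join rule is a design choice; the source analyses do not print one). The
boundary comparison collects per-(TAD, boundary) gene occurrences under the
PT/PG/PP pair category, so a gene at several qualifying boundaries counts
once per occurrence.

## Rank-based tests

The Mann-Whitney/Wilcoxon rank-sum and Kruskal-Wallis statistics are
self-contained implementations: midranks for ties, tie-corrected variance,
a 0.5 continuity correction for the normal approximation, and full
enumeration of label arrangements for tie-free pooled samples of at most 10
(two-sided p = P(|U − E[U]| ≥ |u − E[U]|)). scipy's implementations serve as
independent cross-checks in the tests, never as the computation. Two-sided
throughout; no multiple-testing correction is applied inside the library.
The exact path reproduces enumeration to 1e-12 for every tie-free split with
pooled n ≤ 8. The normal approximation is monotone in |U − E[U]| and agrees
with the exact tail to within 0.02 for balanced small samples; for extreme
splits (one observation versus several) no normal approximation is accurate
to 0.02, which is why the exact path exists. Measured type-I error at
nominal 0.05 is ≈ 0.045–0.057 over 2,000 null simulations at n = 50 per
group (slightly conservative mid-range, as expected with continuity
correction).

## Hi-C operations

Matrices are dense symmetric per-chromosome arrays at fixed resolution,
interchanged as plain-text COO triples (`bin_i  bin_j  count`, upper
triangle). Binary `.hic`/`.cool` containers are out of scope; any such file
can be exported to COO text with e.g. `straw`/`cooler dump` upstream.

**VC_SQRT** divides each entry by sqrt(row sum) × sqrt(column sum);
zero-coverage rows stay zero and are flagged. The result is rescaled by one
constant so the mean of nonzero entries is preserved — a convention only,
since the APA score is scale-invariant (tested).

**Virtual 4C** averages the matrix rows spanned by the viewpoint anchor.
Observed or VC_SQRT counts can be used; the output header records which.

**APA** maps each loop to the pixel (anchor1 midpoint bin i, anchor2
midpoint bin j), skips loops with j − i ≤ 2w (window would cross the
diagonal) or windows leaving the matrix, and averages the (2w+1)² windows
(w = 6 at 25 kb by default). The score is the center pixel over the mean of
the 3×3 block at the lower-left corner — the highest-background corner under
distance decay, so the statistic is conservative (P2LL-style; corner size
configurable). On decay-only matrices the expected score is slightly below
1 (the corner sits ~11 bins nearer the diagonal than the center); with the
default conditions it measures ≈ 0.80–0.99 across seeds, and ≈ 2.6–2.8 with
a 3-fold planted pixel enrichment.

## Synthetic data generator

The generator emulates the statistical assumptions of every downstream
stage on a desk-scale genome. Default study conditions (chosen once):

* 2 chromosomes × 10 Mb at 25 kb resolution; 25 TADs per chromosome tiling
  the chromosome with boundaries on the bin grid (≥ 250 kb each);
* 200 genes, non-overlapping, random strand, lengths log-uniform 2–100 kb
  (genes attached to loop anchors are capped at 20 kb — only their promoter
  participates);
* 100 loops spanning 1.5–4 Mb (so APA windows clear the diagonal), with
  anchor width 10 kb; a planted fraction f = 0.1 of repressive loops
  (standalone p300 peak ≥ 1 kb from any H3K27ac on anchor 1, H3K27me3 peak
  inside a fresh gene's promoter on anchor 2) and a further 0.2 of "active"
  loops (p300-only anchor to an unmarked promoter), which populate the
  non-H3K27me3 comparison group;
* 5 head-to-tail TADs, planted by placing a same-strand gene pair with the
  upstream 3' end at one boundary and the downstream promoter at the other;
* background peaks: 20 extra standalone p300, 30 p300/H3K27ac common pairs,
  40 H3K27ac, 20 H3K27me3;
* expression log2(TPM+1) ~ Normal(μ = 4, σ = 1), with a δ = 1 deficit for
  genes whose promoter carries planted H3K27me3, floored at 0 and
  back-transformed to TPM;
* contacts Poisson with E[C_ij] = N(1+|i−j|)^(−α) × t^[same TAD] ×
  e^[loop pixel], N = 1000, α = 1, t = 1.5, e = 1 (loop pixels are single
  bins, matching APA's pixel-centric aggregation).

In **collision-free mode** (default) every random placement keeps a ≥ 1.1 kb
clearance from every other footprint, boundary windows are reserved against
random gene windows, and loop anchors avoid all peaks they were not planted
with. Consequently the planted signals are recoverable *exactly*: the mark
fraction equals f, the qualifying loop ids equal ground truth, every planted
standalone p300 peak survives the p300-only filter, and exactly n_headtail
TADs pass the detector. Placement is exact (uniform over all admissible
positions given the reservations), so infeasible configurations raise a
capacity error rather than silently truncating. One integer seed drives a
single generator; identical seeds give byte-identical outputs.

What the generator does **not** emulate: overlapping/nested genes and
isoform diversity at one locus, inter-chromosomal contacts, replicate
structure, peak-width and signal-strength distributions of real ChIP-seq,
CTCF-anchored loop geometry, and correlated mark co-occurrence. Passing
recovery tests therefore demonstrates correctness of the interval algebra,
classification rules and statistics under the stated model — not
performance on real, collision-rich genomes, where the mark fraction and
head-to-tail counts depend on the annotation and peak sets supplied.

## Numerical choices and degenerate inputs

* Empty peak/pair inputs raise explicit errors where a statistic is
  undefined (feature distribution, mark fraction, ECDF, rank tests).
* VC_SQRT refuses all-zero matrices; zero rows are flagged, not imputed.
* APA with no surviving loops raises an error listing skip reasons.
* Loop merging keeps the first-encountered representative within a
  center-to-center slack (default one bin) at both anchors.
* Duplicate expression gene ids keep the maximum TPM, with a log line.
* Ties in ranks use midranks; the exact enumeration path requires tie-free
  pooled samples of ≤ 10 observations.

## Problem sizes

Recovery analyses run on 200-loop / 200-gene genomes; calibration loops use
20 seeds (APA null), 100 runs (power), 2,000 runs (type-I), and 1,000
randomized interval cases — sizes at which every check completes in seconds
while keeping Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

* BED-family and plain-text COO inputs only; no GTF/GFF, bigWig, `.hic` or
  `.cool` parsing, no liftover.
* TAD calling, loop calling, insulation scores and ICE/KR balancing are out
  of scope; loops/TADs are inputs.
* Reproducing published genome-wide fractions requires the original pinned
  peak/loop/TAD/expression accessions and a gene annotation; those numbers
  are annotation-dependent and are not computable from the synthetic model.
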