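"""p300-only peak derivation and characterization.

A "p300-only" peak is a p300 ChIP-seq peak that does not overlap any H3K27ac
peak after the H3K27ac set has been extended by +/-1 kb — a candidate
non-classical regulatory site where p300 binds without the activating
acetylation mark.  This module derives those peaks, assigns each peak a single
genomic-feature label (promoter / UTR / exon / intron / downstream /
intergenic, decided at the peak midpoint), and computes signal profiles
around peak centers from bedGraph tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals_io import (
    ChromSizes,
    DataError,
    GeneModel,
    GenomicInterval,
    PeakSet,
    UsageError,
    filter_nonoverlapping,
    slop,
)

FEATURES = (
    "promoter",
    "5'UTR",
    "3'UTR",
    "exon",
    "intron_1st",
    "intron_other",
    "downstream",
    "intergenic",
)
_PRECEDENCE = {f: i for i, f in enumerate(FEATURES)}


@dataclass(frozen=True)
class FeatureAnnotation:
    peak: GenomicInterval
    feature: str
    gene_id: str | None


@dataclass
class ProfileMatrix:
    """regions x bins matrix of mean signal around peak midpoints."""

    matrix: np.ndarray
    bin_width: int
    flank: int

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def derive_p300_only(
    p300: PeakSet,
    h3k27ac: PeakSet,
    sizes: ChromSizes,
    extend: int = 1000,
) -> PeakSet:
    """p300 peaks with no overlap against H3K27ac peaks extended by ``extend``.

    Equivalent to a bedtools slop of the H3K27ac set followed by a whole-peak
    anti-intersection of the p300 set.  The output provably never intersects
    the extended H3K27ac set.
    """
    if extend < 0:
        raise UsageError("extend must be >= 0")
    extended = slop(h3k27ac, extend, sizes)
    out = filter_nonoverlapping(p300, extended)
    out.mark = "p300_only"
    return out


def _feature_for_gene(
    mid: int,
    gene: GeneModel,
    promoter_flank: int,
    downstream_flank: int,
) -> str | None:
    """Feature label of a single position against one gene, or None."""
    if promoter_flank > 0:
        prom = gene.promoter(promoter_flank)
        if prom.start <= mid < prom.end:
            return "promoter"
    if gene.tx_start <= mid < gene.tx_end:
        in_exon = any(s <= mid < e for s, e in gene.exons)
        if in_exon:
            if gene.cds_start is not None and gene.cds_end is not None:
                if mid < gene.cds_start:
                    return "5'UTR" if gene.strand == "+" else "3'UTR"
                if mid >= gene.cds_end:
                    return "3'UTR" if gene.strand == "+" else "5'UTR"
            return "exon"
        introns = gene.introns()
        for k, (s, e) in enumerate(introns):
            if s <= mid < e:
                # intron numbering follows transcription order: on the minus
                # strand intron 1 is the highest-coordinate intron
                number = k + 1 if gene.strand == "+" else len(introns) - k
                return "intron_1st" if number == 1 else "intron_other"
        return "exon"  # unreachable for well-formed exon structure
    # downstream window past the TES in transcription direction
    if gene.strand == "+":
        if gene.tx_end <= mid < gene.tx_end + downstream_flank:
            return "downstream"
    else:
        if gene.tx_start - downstream_flank <= mid < gene.tx_start:
            return "downstream"
    return None


def annotate_feature(
    peak: GenomicInterval,
    genes: list[GeneModel],
    promoter_flank: int = 1000,
    downstream_flank: int = 5000,
) -> FeatureAnnotation:
    """Assign one feature label to a peak, decided at its midpoint.

    Precedence: promoter > 5'UTR > 3'UTR > exon > intron > downstream >
    intergenic, evaluated over all genes on the peak's chromosome; the gene
    supplying the winning label is reported.  A peak on a chromosome with no
    genes is intergenic.
    """
    mid = peak.midpoint
    best: tuple[int, str, str | None] = (_PRECEDENCE["intergenic"], "intergenic", None)
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        label = _feature_for_gene(mid, gene, promoter_flank, downstream_flank)
        if label is not None and _PRECEDENCE[label] < best[0]:
            best = (_PRECEDENCE[label], label, gene.gene_id)
    return FeatureAnnotation(peak, best[1], best[2])


def feature_distribution(
    peaks: PeakSet,
    genes: list[GeneModel],
    promoter_flank: int = 1000,
    downstream_flank: int = 5000,
) -> dict[str, float]:
    """Proportion of peaks per feature label; proportions sum to 1."""
    if len(peaks) == 0:
        raise DataError("feature distribution of an empty peak set is undefined")
    counts: dict[str, int] = {}
    for peak in peaks:
        ann = annotate_feature(peak, genes, promoter_flank, downstream_flank)
        counts[ann.feature] = counts.get(ann.feature, 0) + 1
    n = len(peaks)
    return {f: c / n for f, c in counts.items()}


def signal_profile(
    track: list[tuple[str, int, int, float]],
    centers: PeakSet,
    flank: int = 5000,
    bin_width: int = 50,
) -> ProfileMatrix:
    """Mean bedGraph signal in fixed-width bins around each peak midpoint.

    The window is ``[mid - flank, mid + flank)``; positions not covered by the
    track (including positions past a chromosome end) contribute 0.
    """
    if flank <= 0 or bin_width <= 0 or (2 * flank) % bin_width:
        raise UsageError("bin_width must divide 2*flank")
    n_bins = 2 * flank // bin_width
    # per-chromosome sorted arrays for binary search
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {r[0] for r in track}:
        rows = [r for r in track if r[0] == chrom]
        rows.sort(key=lambda r: r[1])
        by_chrom[chrom] = (
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
            np.array([r[3] for r in rows]),
        )
    mat = np.zeros((len(centers), n_bins))
    for ri, peak in enumerate(centers):
        if peak.chrom not in by_chrom:
            continue
        starts, ends, vals = by_chrom[peak.chrom]
        w_start = peak.midpoint - flank
        for b in range(n_bins):
            b_start = w_start + b * bin_width
            b_end = b_start + bin_width
            lo = np.searchsorted(ends, max(b_start, 0), side="right")
            hi = np.searchsorted(starts, b_end, side="left")
            total = 0.0
            for i in range(lo, hi):
                ov = min(ends[i], b_end) - max(starts[i], b_start)
                if ov > 0:
                    total += ov * vals[i]
            mat[ri, b] = total / bin_width
    return ProfileMatrix(mat, bin_width, flank)
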