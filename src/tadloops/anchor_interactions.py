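"""Loop-anchor / TAD-boundary annotation and interaction-category censuses.

Each anchor (a loop anchor or a +/-5 kb TAD-boundary window) is annotated
with a gene feature — promoter (TSS +/-1 kb), terminator (TES +/-5 kb), gene
body, or intergenic — and with flags for overlap with p300-only and H3K27me3
peaks.  Pairs of anchors are classified into unordered interaction categories
(e.g. "Genebody-Promoter", "H3K27me3-p300only"); the census of these
categories and the fraction of pairs anchored by a p300-only peak on one side
and H3K27me3 on the other are the module's genome-wide summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .intervals_io import (
    ChromSizes,
    DataError,
    GeneModel,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    TadSet,
    UsageError,
    overlaps_any,
)

_DISPLAY = {
    "promoter": "Promoter",
    "terminator": "Terminator",
    "gene_body": "Genebody",
    "intergenic": "Intergenic",
}


@dataclass(frozen=True)
class AnchorAnnotation:
    anchor: GenomicInterval
    gene_feature: str  # promoter | terminator | gene_body | intergenic
    gene_ids: tuple[str, ...]
    has_p300_only: bool
    has_h3k27me3: bool

    @property
    def display_class(self) -> str:
        """Category label for this anchor: mark flags take precedence over
        gene features (p300only > H3K27me3 > gene feature)."""
        if self.has_p300_only:
            return "p300only"
        if self.has_h3k27me3:
            return "H3K27me3"
        return _DISPLAY[self.gene_feature]


@dataclass(frozen=True)
class BoundaryPair:
    tad: GenomicInterval
    left_boundary: GenomicInterval
    right_boundary: GenomicInterval
    left_annotation: AnchorAnnotation
    right_annotation: AnchorAnnotation


def tad_boundaries(
    tads: TadSet, sizes: ChromSizes, flank: int = 5000
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """The (left, right) +/-flank boundary windows of every TAD, clipped to
    the chromosome.  Exactly two windows per TAD; windows of abutting TADs
    may overlap each other."""
    if flank <= 0:
        raise UsageError("boundary flank must be > 0")
    out = []
    for tad in tads:
        if tad.chrom not in sizes:
            raise DataError(f"chromosome {tad.chrom!r} missing from chrom sizes")
        length = sizes[tad.chrom]
        left = GenomicInterval(
            tad.chrom, max(0, tad.start - flank), min(length, tad.start + flank)
        )
        right = GenomicInterval(
            tad.chrom, max(0, tad.end - flank), min(length, tad.end + flank)
        )
        out.append((left, right))
    return out


def merge_loops(loop_sets: list[LoopSet], slack: int) -> LoopSet:
    """Collapse near-duplicate loops across files.

    Two loops are duplicates when both anchor centers lie within ``slack`` bp
    (center-to-center) of an already-kept loop's corresponding anchors; the
    first-encountered representative is kept.
    """
    if slack < 0:
        raise UsageError("slack must be >= 0")
    kept: list[Loop] = []
    for ls in loop_sets:
        for lp in ls:
            c1, c2 = lp.anchor1.midpoint, lp.anchor2.midpoint
            dup = False
            for k in kept:
                if (
                    lp.anchor1.chrom == k.anchor1.chrom
                    and lp.anchor2.chrom == k.anchor2.chrom
                    and abs(c1 - k.anchor1.midpoint) <= slack
                    and abs(c2 - k.anchor2.midpoint) <= slack
                ):
                    dup = True
                    break
            if not dup:
                kept.append(lp)
    return LoopSet(kept)


def annotate_anchor(
    anchor: GenomicInterval,
    genes: list[GeneModel],
    p300_only: PeakSet,
    h3k27me3: PeakSet,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
) -> AnchorAnnotation:
    """Annotate one anchor against gene features and peak marks.

    Gene feature precedence is promoter > terminator > gene_body over all
    genes whose windows intersect the anchor; mark flags are >= 1 bp overlap
    with the respective peak sets and are independent of the gene feature.
    """
    promoter_genes: list[str] = []
    terminator_genes: list[str] = []
    body_genes: list[str] = []
    for gene in genes:
        if gene.chrom != anchor.chrom:
            continue
        if anchor.overlaps(gene.promoter(promoter_flank)):
            promoter_genes.append(gene.gene_id)
        elif anchor.overlaps(gene.terminator(terminator_flank)):
            terminator_genes.append(gene.gene_id)
        elif anchor.overlaps(gene.span()):
            body_genes.append(gene.gene_id)
    if promoter_genes:
        feature, ids = "promoter", promoter_genes
    elif terminator_genes:
        feature, ids = "terminator", terminator_genes
    elif body_genes:
        feature, ids = "gene_body", body_genes
    else:
        feature, ids = "intergenic", []
    return AnchorAnnotation(
        anchor,
        feature,
        tuple(sorted(set(ids))),
        has_p300_only=overlaps_any(anchor, p300_only),
        has_h3k27me3=overlaps_any(anchor, h3k27me3),
    )


def classify_interaction(a1: AnchorAnnotation, a2: AnchorAnnotation) -> str:
    """Unordered pair label of the two anchors' display classes,
    e.g. ``Genebody-Promoter`` or ``H3K27me3-p300only``."""
    return "-".join(sorted((a1.display_class, a2.display_class)))


def interaction_census(
    pairs: list[tuple[AnchorAnnotation, AnchorAnnotation]],
) -> dict[str, int]:
    """Counts of interaction categories over all pairs; counts sum to |pairs|."""
    return dict(Counter(classify_interaction(a1, a2) for a1, a2 in pairs))


def pair_has_p300_h3k27me3(
    a1: AnchorAnnotation, a2: AnchorAnnotation, same_anchor: bool = False
) -> bool:
    """Whether a pair is anchored by a p300-only peak and H3K27me3.

    By default the two marks must sit on opposite anchors; ``same_anchor=True``
    additionally accepts both marks co-occurring on one anchor.
    """
    opposite = (a1.has_p300_only and a2.has_h3k27me3) or (
        a2.has_p300_only and a1.has_h3k27me3
    )
    if same_anchor:
        return opposite or (a1.has_p300_only and a1.has_h3k27me3) or (
            a2.has_p300_only and a2.has_h3k27me3
        )
    return opposite


def mark_fraction(
    pairs: list[tuple[AnchorAnnotation, AnchorAnnotation]],
    same_anchor: bool = False,
) -> tuple[float, str]:
    """Fraction of pairs anchored by p300-only and H3K27me3 (opposite
    anchors), returned with its 2-decimal percent rendering."""
    if not pairs:
        raise DataError("mark fraction of zero pairs is undefined")
    n_hit = sum(1 for a1, a2 in pairs if pair_has_p300_h3k27me3(a1, a2, same_anchor))
    frac = n_hit / len(pairs)
    return frac, f"{100 * frac:.2f}%"


def annotate_loops(
    loops: LoopSet,
    genes: list[GeneModel],
    p300_only: PeakSet,
    h3k27me3: PeakSet,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
) -> list[tuple[AnchorAnnotation, AnchorAnnotation]]:
    """Annotate both anchors of every intra-chromosomal loop."""
    out = []
    for lp in loops.intra_chromosomal():
        a1 = annotate_anchor(
            lp.anchor1, genes, p300_only, h3k27me3, promoter_flank, terminator_flank
        )
        a2 = annotate_anchor(
            lp.anchor2, genes, p300_only, h3k27me3, promoter_flank, terminator_flank
        )
        out.append((a1, a2))
    return out


def annotate_boundaries(
    tads: TadSet,
    sizes: ChromSizes,
    genes: list[GeneModel],
    p300_only: PeakSet,
    h3k27me3: PeakSet,
    boundary_flank: int = 5000,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
) -> list[BoundaryPair]:
    """Annotate the (left, right) boundary-window pair of every TAD.

    A TAD "boundary interaction" is the pair of that TAD's own two windows;
    each TAD is treated independently even when abutting TADs share windows.
    """
    out = []
    for tad, (left, right) in zip(
        tads, tad_boundaries(tads, sizes, boundary_flank)
    ):
        la = annotate_anchor(
            left, genes, p300_only, h3k27me3, promoter_flank, terminator_flank
        )
        ra = annotate_anchor(
            right, genes, p300_only, h3k27me3, promoter_flank, terminator_flank
        )
        out.append(BoundaryPair(tad, left, right, la, ra))
    return out
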