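"""Head-to-tail TAD-boundary gene-pair detection and oncogene scanning.

A head-to-tail pair is two same-strand genes anchoring the two boundaries of
one TAD: in transcription order the upstream gene's 3' end (terminator
window, TES +/-5 kb) overlaps one boundary window and the downstream gene's
promoter (TSS +/-1 kb) overlaps the partner window — the Dcbld2–Cpox /
CDK12–PSMD3 conformation, in which the downstream gene restrains the
upstream one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals_io import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    TadSet,
    UsageError,
)
from .anchor_interactions import tad_boundaries


@dataclass(frozen=True)
class BoundaryGeneFeatures:
    """Per-boundary gene-feature call for one TAD (P/T/G/none per side)."""

    tad: GenomicInterval
    left_feature: str  # one of P, T, G, none
    right_feature: str
    left_genes: tuple[str, ...]
    right_genes: tuple[str, ...]

    @property
    def pair_category(self) -> str | None:
        """Two-letter category (PP/PT/PG/TT/TG/GG, ordered P before T before
        G) when both boundaries carry a gene feature, else None."""
        if self.left_feature == "none" or self.right_feature == "none":
            return None
        order = {"P": 0, "T": 1, "G": 2}
        return "".join(
            sorted((self.left_feature, self.right_feature), key=order.get)
        )


@dataclass(frozen=True)
class HeadTailPair:
    tad: GenomicInterval
    upstream_gene: GeneModel
    downstream_gene: GeneModel
    pair_category: str

    @property
    def same_strand(self) -> bool:
        return self.upstream_gene.strand == self.downstream_gene.strand


def _boundary_feature(
    window: GenomicInterval,
    genes: list[GeneModel],
    promoter_flank: int,
    terminator_flank: int,
) -> tuple[str, tuple[str, ...]]:
    """P if any promoter window intersects, else T, else G, else none."""
    p, t, g = [], [], []
    for gene in genes:
        if gene.chrom != window.chrom:
            continue
        if window.overlaps(gene.promoter(promoter_flank)):
            p.append(gene.gene_id)
        elif window.overlaps(gene.terminator(terminator_flank)):
            t.append(gene.gene_id)
        elif window.overlaps(gene.span()):
            g.append(gene.gene_id)
    for label, ids in (("P", p), ("T", t), ("G", g)):
        if ids:
            return label, tuple(sorted(set(ids)))
    return "none", ()


def boundary_gene_pairs(
    tads: TadSet,
    genes: list[GeneModel],
    sizes: ChromSizes,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
    boundary_flank: int = 5000,
) -> list[BoundaryGeneFeatures]:
    """Per-TAD boundary gene features (precedence P > T > G per boundary).

    TADs where both boundary windows carry a gene feature yield a categorized
    pair (PP, PT, PG, ...); others have ``pair_category`` None.
    """
    out = []
    for tad, (left, right) in zip(
        tads, tad_boundaries(tads, sizes, boundary_flank)
    ):
        lf, lg = _boundary_feature(left, genes, promoter_flank, terminator_flank)
        rf, rg = _boundary_feature(right, genes, promoter_flank, terminator_flank)
        out.append(BoundaryGeneFeatures(tad, lf, rf, lg, rg))
    return out


def detect_head_to_tail(
    tads: TadSet,
    genes: list[GeneModel],
    sizes: ChromSizes,
    promoter_flank: int = 1000,
    terminator_flank: int = 5000,
    boundary_flank: int = 5000,
    allow_gene_body_3prime: bool = False,
) -> list[HeadTailPair]:
    """Detect head-to-tail gene pairs at TAD boundaries.

    A pair (g1 upstream, g2 downstream, in transcription direction) is
    emitted for a TAD when the genes share a strand, g1's terminator window
    overlaps one boundary window, and g2's promoter window overlaps the other
    boundary window of the same TAD.  On the plus strand g1 sits at the left
    boundary and g2 at the right; on the minus strand the geometry mirrors.
    ``allow_gene_body_3prime`` additionally accepts g1's gene body (rather
    than only its terminator window) overlapping the boundary.  One record
    per (TAD, g1, g2) combination, isoforms deduplicated by gene id.
    """
    results: list[HeadTailPair] = []
    seen: set[tuple[int, str, str]] = set()
    windows = tad_boundaries(tads, sizes, boundary_flank)
    for ti, (tad, (left, right)) in enumerate(zip(tads, windows)):
        chrom_genes = [g for g in genes if g.chrom == tad.chrom]
        lf, _ = _boundary_feature(left, chrom_genes, promoter_flank, terminator_flank)
        rf, _ = _boundary_feature(right, chrom_genes, promoter_flank, terminator_flank)
        order = {"P": 0, "T": 1, "G": 2}
        category = (
            "".join(sorted((lf, rf), key=order.get))
            if "none" not in (lf, rf)
            else "PT"
        )
        for strand in ("+", "-"):
            # transcription direction: upstream gene precedes downstream gene
            if strand == "+":
                term_window, prom_window = left, right
            else:
                term_window, prom_window = right, left
            ups = [
                g for g in chrom_genes
                if g.strand == strand and (
                    term_window.overlaps(g.terminator(terminator_flank))
                    or (allow_gene_body_3prime and term_window.overlaps(g.span()))
                )
            ]
            downs = [
                g for g in chrom_genes
                if g.strand == strand
                and prom_window.overlaps(g.promoter(promoter_flank))
            ]
            for g1 in ups:
                for g2 in downs:
                    if g1.gene_id == g2.gene_id:
                        continue
                    # upstream must precede downstream in transcription order
                    if strand == "+" and g1.tx_start >= g2.tx_start:
                        continue
                    if strand == "-" and g1.tx_end <= g2.tx_end:
                        continue
                    key = (ti, g1.gene_id, g2.gene_id)
                    if key in seen:
                        continue
                    seen.add(key)
                    results.append(HeadTailPair(tad, g1, g2, pair_category=category))
    return results


def oncogene_scan(
    pairs: list[HeadTailPair], oncogenes: set[str]
) -> tuple[list[HeadTailPair], float]:
    """Head-to-tail pairs whose upstream gene is a listed oncogene, and the
    fraction of the oncogene list placed in that repressible position."""
    if not oncogenes:
        raise UsageError("oncogene list must be non-empty")
    hits = [p for p in pairs if p.upstream_gene.gene_id in oncogenes]
    placed = {p.upstream_gene.gene_id for p in hits}
    return hits, len(placed) / len(oncogenes)
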