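"""Synthetic genome generator with planted chromatin structure.

Produces a complete toy dataset — gene models, p300/H3K27ac/H3K27me3 peak
sets, TADs tiling each chromosome, a loop set with a planted fraction of
p300-only <-> H3K27me3 anchor pairs, head-to-tail TAD-boundary gene pairs,
a two-group expression model on the log2(TPM+1) scale, and Poisson contact
matrices with distance decay, TAD blocks and enriched loop pixels — together
with the ground truth needed for recovery tests.

In collision-free mode (the default) every random placement keeps a clearance
margin from every planted structure, so the planted signals are recoverable
exactly: standalone p300 peaks survive the p300-only filter, only planted
loops qualify as p300-only/H3K27me3 pairs, and only planted TADs carry a
head-to-tail gene pair.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .intervals_io import (
    DataError,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    TadSet,
    write_chrom_sizes,
    write_expression,
    write_genes,
    write_intervals,
    write_pairs,
)
from .hic_ops import ContactMatrix, write_matrix


class CapacityError(DataError):
    """Requested structures exceed chromosome capacity; never silently truncated."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Scales are chosen to resemble a mammalian chromosome arm at Hi-C loop
    resolution: 10 Mb chromosomes binned at 25 kb, TADs of a few hundred kb,
    loops spanning 1.5-4 Mb so APA windows clear the diagonal, and expression
    following log2(TPM+1) ~ Normal(mu_hi, sigma) with a deficit of
    ``expr_delta`` for genes whose promoter carries planted H3K27me3.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    resolution: int = 25_000
    n_genes: int = 200
    n_tads: int = 50
    n_loops: int = 100
    planted_fraction: float = 0.1
    active_fraction: float = 0.2  # p300-only <-> unmarked-promoter loops
    n_headtail: int = 5
    expr_mu_hi: float = 4.0
    expr_sigma: float = 1.0
    expr_delta: float = 1.0
    decay_alpha: float = 1.0
    loop_enrichment: float = 1.0
    tad_enrichment: float = 1.5
    total_contacts: float = 1000.0
    collision_free: bool = True
    # structural details
    anchor_width: int = 10_000
    min_loop_span: int = 1_500_000
    max_loop_span: int = 4_000_000
    p300_width: int = 300
    h3k27ac_width: int = 600
    h3k27me3_width: int = 800
    n_p300_extra: int = 20
    n_p300_common: int = 30
    n_h3k27ac_extra: int = 40
    n_h3k27me3_extra: int = 20
    promoter_flank: int = 1000
    terminator_flank: int = 5000
    boundary_flank: int = 5000

    def __post_init__(self) -> None:
        if not (0 <= self.planted_fraction <= 1):
            raise DataError("planted_fraction must be in [0, 1]")
        if self.chrom_length % self.resolution:
            raise DataError("resolution must divide chrom_length")
        for name in ("n_chroms", "n_genes", "n_tads", "n_loops", "n_headtail"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")

    @property
    def n_planted_loops(self) -> int:
        return round(self.planted_fraction * self.n_loops)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    planted_loop_ids: list[str]
    headtail_tad_ids: list[str]
    gene_group: dict[str, str]  # gene_id -> repressed | background
    loop_pixels: dict[str, tuple[str, int, int]]  # loop id -> (chrom, bin i, bin j)
    p300_only_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    peaks: dict[str, PeakSet]  # p300, h3k27ac, h3k27me3
    tads: TadSet
    loops: LoopSet
    expression: ExpressionTable
    ground_truth: GroundTruth
    chrom_sizes: dict[str, int]


class _Registry:
    """Per-chromosome reserved footprints with a global clearance pad.

    A candidate footprint is admissible when it stays >= pad bp away from
    every reservation, which guarantees mutual clearance between random
    placements and planted structures (e.g. the > 1 kb gap that keeps
    standalone p300 peaks out of extended H3K27ac regions).
    """

    def __init__(self, chroms: list[str], pad: int):
        self.pad = pad
        self._starts: dict[str, list[int]] = {c: [] for c in chroms}
        self._ends: dict[str, list[int]] = {c: [] for c in chroms}

    # no footprint in this generator exceeds ~120 kb; bounding the backward
    # scan by this span keeps the admissibility check correct and O(log n)
    MAX_FOOTPRINT = 150_000

    def free(self, chrom: str, start: int, end: int) -> bool:
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = bisect_left(starts, end + self.pad)
        k = i - 1
        while k >= 0 and starts[k] > start - self.MAX_FOOTPRINT - self.pad:
            if ends[k] + self.pad > start:
                return False
            k -= 1
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        i = bisect_left(self._starts[chrom], start)
        self._starts[chrom].insert(i, start)
        self._ends[chrom].insert(i, end)


def _sample(
    rng: np.random.Generator,
    registry: _Registry,
    chrom: str,
    span: int,
    lo: int,
    hi: int,
) -> int | None:
    """Start position for a ``span`` bp footprint in [lo, hi), sampled
    uniformly over all admissible positions, or None when the chromosome has
    no room.  Does not reserve."""
    pad = registry.pad
    merged: list[tuple[int, int]] = []
    for s, e in sorted(zip(registry._starts[chrom], registry._ends[chrom])):
        s, e = s - pad, e + pad
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    # gaps between reservations, clipped to [lo, hi - span]
    choices: list[tuple[int, int]] = []  # (first admissible start, count)
    cursor = lo
    for s, e in merged + [(hi, hi)]:
        gap_lo, gap_hi = cursor, min(s, hi)
        first, last = gap_lo, gap_hi - span
        if last >= first:
            choices.append((first, last - first + 1))
        cursor = max(cursor, e)
        if cursor >= hi:
            break
    total = sum(c for _, c in choices)
    if total == 0:
        return None
    pick = int(rng.integers(total))
    for first, count in choices:
        if pick < count:
            return first + pick
        pick -= count
    raise AssertionError("unreachable")


def _place(
    rng: np.random.Generator,
    registry: _Registry,
    chrom: str,
    span: int,
    lo: int,
    hi: int,
) -> int:
    """Like :func:`_sample` but reserves the footprint; raises
    :class:`CapacityError` when nothing fits."""
    start = _sample(rng, registry, chrom, span, lo, hi)
    if start is None:
        raise CapacityError(f"no room for a {span} bp footprint on {chrom}")
    registry.reserve(chrom, start, start + span)
    return start


def _gene_length(rng: np.random.Generator, lo: int = 2_000, hi: int = 100_000) -> int:
    """Log-uniform in [lo, hi] (default 2-100 kb)."""
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _make_tads(config: SyntheticConfig, rng: np.random.Generator) -> TadSet:
    """Tile each chromosome with TADs whose boundaries sit on the bin grid."""
    per_chrom = config.n_tads // config.n_chroms
    if per_chrom < 1:
        raise CapacityError("need at least one TAD per chromosome")
    n_bins = config.chrom_length // config.resolution
    min_bins = 10  # >= 250 kb at 25 kb resolution
    if per_chrom * min_bins > n_bins:
        raise CapacityError(
            f"{per_chrom} TADs of >= {min_bins} bins do not fit in {n_bins} bins"
        )
    domains = []
    for ci, chrom in enumerate(config.chrom_names):
        # widths = minimum size plus a random split of the remaining bins
        extra = rng.multinomial(n_bins - per_chrom * min_bins,
                                np.full(per_chrom, 1.0 / per_chrom))
        widths = min_bins + extra
        edges = np.concatenate([[0], np.cumsum(widths)])
        for k in range(per_chrom):
            domains.append(
                GenomicInterval(
                    chrom,
                    int(edges[k]) * config.resolution,
                    int(edges[k + 1]) * config.resolution,
                    name=f"tad_{chrom}_{k}",
                )
            )
    return TadSet(domains)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names
    sizes = {c: config.chrom_length for c in chroms}
    pad = 1100 if config.collision_free else 10
    registry = _Registry(chroms, pad)

    tads = _make_tads(config, rng)
    tads_by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chroms}
    for t in tads:
        tads_by_chrom[t.chrom].append(t)

    # reserve every boundary window so random structures keep clear of them
    if config.collision_free:
        for t in tads:
            for b in (t.start, t.end):
                registry.reserve(
                    t.chrom,
                    max(0, b - config.boundary_flank),
                    min(config.chrom_length, b + config.boundary_flank),
                )

    genes: list[GeneModel] = []
    p300: list[GenomicInterval] = []
    h3k27ac: list[GenomicInterval] = []
    h3k27me3: list[GenomicInterval] = []
    loops: list[Loop] = []

    # ---- head-to-tail plants: same-strand gene pairs bracketing one TAD ----
    eligible = [
        t for t in tads
        if t.start >= 200_000 and t.end <= config.chrom_length - 200_000
    ]
    # keep planted TADs non-adjacent so the flanking genes cannot collide
    eligible = eligible[::2]
    if config.n_headtail > len(eligible):
        raise CapacityError(
            f"cannot plant {config.n_headtail} head-to-tail TADs; "
            f"only {len(eligible)} eligible"
        )
    pick = rng.choice(len(eligible), config.n_headtail, replace=False)
    headtail_tad_ids = []
    for idx in sorted(int(i) for i in pick):
        tad = eligible[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        len1, len2 = _gene_length(rng), _gene_length(rng)
        k = len(headtail_tad_ids)
        if strand == "+":
            g1 = GeneModel(tad.chrom, "+", tad.start - len1, tad.start, f"ht_up_{k}")
            g2 = GeneModel(tad.chrom, "+", tad.end, tad.end + len2, f"ht_down_{k}")
        else:
            g1 = GeneModel(tad.chrom, "-", tad.end, tad.end + len1, f"ht_up_{k}")
            g2 = GeneModel(tad.chrom, "-", tad.start - len2, tad.start, f"ht_down_{k}")
        for g in (g1, g2):
            registry.reserve(g.chrom, g.tx_start - 6000, g.tx_end + 6000)
            genes.append(g)
        headtail_tad_ids.append(tad.name)

    # ---- random genes (largest first, so big genes find room) ----
    n_planted = config.n_planted_loops
    n_active = round(config.active_fraction * config.n_loops)
    if n_planted + n_active > config.n_loops:
        raise CapacityError("planted_fraction + active_fraction exceeds 1")
    n_random_genes = config.n_genes - len(genes) - n_planted - n_active
    if n_random_genes < 0:
        raise CapacityError(
            f"n_genes={config.n_genes} is smaller than the number of genes "
            "required by the planted structures"
        )
    draws = [
        (gi, chroms[gi % len(chroms)], _gene_length(rng),
         "+" if rng.random() < 0.5 else "-")
        for gi in range(n_random_genes)
    ]
    for gi, chrom, glen, strand in sorted(draws, key=lambda d: -d[2]):
        s = _place(rng, registry, chrom, glen + 12_000, 1_000,
                   config.chrom_length - 1_000)
        genes.append(
            GeneModel(chrom, strand, s + 6000, s + 6000 + glen, f"gene_{gi:04d}")
        )

    # ---- loops: planted p300-only <-> H3K27me3 pairs first, then background ----
    half_anchor = config.anchor_width // 2
    margin = 8 * config.resolution + half_anchor  # APA windows must fit
    planted_loop_ids: list[str] = []
    repressed_genes: list[str] = []
    loop_pixels: dict[str, tuple[str, int, int]] = {}
    p300_only_ids: list[str] = []

    def place_anchor_pair(chrom: str, gene_length: int = 0) -> tuple[int, int]:
        """Centers (c1, c2) of a loop's two anchors with free footprints;
        a planted loop's anchor2 footprint also covers its promoter gene.
        Anchor1 is sampled exactly, then anchor2 exactly within the allowed
        genomic span window."""
        f2_span = half_anchor + max(half_anchor, gene_length + 6000)
        for _ in range(60):
            s1 = _sample(
                rng, registry, chrom, config.anchor_width,
                margin - half_anchor,
                config.chrom_length - config.min_loop_span - margin,
            )
            if s1 is None:
                break
            c1 = s1 + half_anchor
            hi_c2 = min(
                c1 + config.max_loop_span,
                config.chrom_length - margin,
                config.chrom_length - gene_length - 7000,
            )
            s2 = _sample(
                rng, registry, chrom, f2_span,
                c1 + config.min_loop_span - half_anchor,
                hi_c2 - half_anchor + f2_span,
            )
            if s2 is None:
                continue
            c2 = s2 + half_anchor
            registry.reserve(chrom, s1, s1 + config.anchor_width)
            registry.reserve(chrom, s2, s2 + f2_span)
            return c1, c2
        raise CapacityError(f"could not place a loop on {chrom}")

    for li in range(config.n_loops):
        chrom = chroms[li % len(chroms)]
        repressive = li < n_planted
        active = n_planted <= li < n_planted + n_active
        # looped genes stay short; only their promoter matters here
        glen = _gene_length(rng, hi=20_000) if (repressive or active) else 0
        c1, c2 = place_anchor_pair(chrom, glen)
        name = f"loop_{li:04d}"
        a1 = GenomicInterval(chrom, c1 - half_anchor, c1 + half_anchor)
        a2 = GenomicInterval(chrom, c2 - half_anchor, c2 + half_anchor)
        if repressive or active:
            # anchor1: standalone p300 peak at the anchor center
            pw = config.p300_width
            pid = f"p300_only_{len(p300_only_ids)}"
            p300.append(
                GenomicInterval(chrom, c1 - pw // 2, c1 - pw // 2 + pw, name=pid)
            )
            p300_only_ids.append(pid)
            # anchor2: a fresh gene's promoter; repressive loops additionally
            # carry an H3K27me3 peak inside that promoter window
            gid = f"looped_{li}"
            gene = GeneModel(chrom, "+", c2, c2 + glen, gid)
            genes.append(gene)
            if repressive:
                mw = config.h3k27me3_width
                h3k27me3.append(
                    GenomicInterval(chrom, c2 - mw // 2, c2 - mw // 2 + mw,
                                    name=f"h3k27me3_planted_{li}")
                )
                repressed_genes.append(gid)
                planted_loop_ids.append(name)
        loops.append(Loop(a1, a2, name=name))
        loop_pixels[name] = (
            chrom, c1 // config.resolution, c2 // config.resolution
        )

    # ---- background peaks ----
    def place_peak(kind: str, width: int, k: int) -> GenomicInterval:
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = _place(rng, registry, chrom, width, 1_000, config.chrom_length - 1_000)
        return GenomicInterval(chrom, s, s + width, name=f"{kind}_{k}")

    for k in range(config.n_p300_extra):
        iv = place_peak("p300_only_extra", config.p300_width, k)
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"p300_only_{len(p300_only_ids)}")
        p300.append(iv)
        p300_only_ids.append(iv.name)
    for k in range(config.n_p300_common):
        # a p300 peak overlapping an H3K27ac peak (classical enhancer-like)
        chrom = chroms[int(rng.integers(len(chroms)))]
        w = config.h3k27ac_width
        s = _place(rng, registry, chrom, w, 1_000, config.chrom_length - 1_000)
        h3k27ac.append(GenomicInterval(chrom, s, s + w, name=f"h3k27ac_common_{k}"))
        off = (w - config.p300_width) // 2
        p300.append(
            GenomicInterval(chrom, s + off, s + off + config.p300_width,
                            name=f"p300_common_{k}")
        )
    for k in range(config.n_h3k27ac_extra):
        h3k27ac.append(place_peak("h3k27ac", config.h3k27ac_width, k))
    for k in range(config.n_h3k27me3_extra):
        h3k27me3.append(place_peak("h3k27me3", config.h3k27me3_width, k))

    # ---- expression: two-group normal model on the log2(TPM+1) scale ----
    repressed = set(repressed_genes)
    tpm: dict[str, float] = {}
    for g in genes:
        mu = config.expr_mu_hi - (config.expr_delta if g.gene_id in repressed else 0.0)
        x = max(0.0, float(rng.normal(mu, config.expr_sigma)))
        tpm[g.gene_id] = 2.0**x - 1.0

    gene_group = {
        g.gene_id: ("repressed" if g.gene_id in repressed else "background")
        for g in genes
    }

    truth = GroundTruth(
        planted_loop_ids=planted_loop_ids,
        headtail_tad_ids=headtail_tad_ids,
        gene_group=gene_group,
        loop_pixels={k: loop_pixels[k] for k in sorted(loop_pixels)},
        p300_only_ids=p300_only_ids,
    )
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return SyntheticDataset(
        config=config,
        genes=genes,
        peaks={
            "p300": PeakSet(p300, mark="p300"),
            "h3k27ac": PeakSet(h3k27ac, mark="H3K27ac"),
            "h3k27me3": PeakSet(h3k27me3, mark="H3K27me3"),
        },
        tads=tads,
        loops=LoopSet(loops),
        expression=ExpressionTable(tpm),
        ground_truth=truth,
        chrom_sizes=sizes,
    )


def generate_contact_matrix(
    config: SyntheticConfig,
    tads: TadSet,
    loops: LoopSet,
    chrom: str,
    rng: np.random.Generator | None = None,
) -> ContactMatrix:
    """Poisson contact matrix for one chromosome.

    Expected counts follow N * (1 + |i-j|)^(-alpha), multiplied by
    ``tad_enrichment`` when bins i and j fall in the same TAD and by
    ``loop_enrichment`` at each loop's anchor-midpoint pixel.  Counts are
    Poisson-sampled on the upper triangle and mirrored, so the matrix is
    symmetric with integer entries.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    res = config.resolution
    n_bins = config.chrom_length // res
    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    expected = config.total_contacts * (1.0 + d) ** (-config.decay_alpha)

    tad_id = np.full(n_bins, -1)
    for k, t in enumerate(t for t in tads if t.chrom == chrom):
        if t.start % res or t.end % res:
            raise DataError("TAD boundaries must align to the matrix resolution")
        tad_id[t.start // res : t.end // res] = k
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    expected = np.where(same, expected * config.tad_enrichment, expected)

    for lp in loops:
        if lp.inter_chromosomal or lp.anchor1.chrom != chrom:
            continue
        i = lp.anchor1.midpoint // res
        j = lp.anchor2.midpoint // res
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise DataError(f"loop {lp.name} outside the matrix span")
        expected[i, j] *= config.loop_enrichment
        expected[j, i] *= config.loop_enrichment

    upper = np.triu(rng.poisson(expected)).astype(float)
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom, res, counts)


def write_dataset(ds: SyntheticDataset, outdir: str | Path,
                  with_matrices: bool = True) -> None:
    """Write the dataset in the plain-text interchange formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genes(ds.genes, out / "genes.bed12")
    write_intervals(ds.peaks["p300"], out / "p300.narrowPeak", "narrowPeak")
    write_intervals(ds.peaks["h3k27ac"], out / "h3k27ac.narrowPeak", "narrowPeak")
    write_intervals(ds.peaks["h3k27me3"], out / "h3k27me3.narrowPeak", "narrowPeak")
    with open(out / "tads.bed", "wt") as fh:
        for t in ds.tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.name or '.'}\n")
    write_pairs(ds.loops, out / "loops.bedpe")
    write_expression(ds.expression, out / "expression.tsv")
    write_chrom_sizes(ds.chrom_sizes, out / "chrom.sizes")
    (out / "ground_truth.json").write_text(ds.ground_truth.to_json())
    if with_matrices:
        for chrom in ds.config.chrom_names:
            cm = generate_contact_matrix(ds.config, ds.tads, ds.loops, chrom)
            write_matrix(cm, out / f"matrix_{chrom}.coo.tsv")
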