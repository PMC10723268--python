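"""Interval data model, format round-trips, and interval algebra.

The algebra operations are checked against a per-base bit-vector oracle on
toy chromosomes, which is the ground truth for half-open overlap semantics.
"""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tadloops.intervals_io import (
    DataError,
    GeneModel,
    GenomicInterval,
    ParseError,
    PeakSet,
    TadSet,
    filter_nonoverlapping,
    merge_intervals,
    overlaps_any,
    read_expression,
    read_genes,
    read_intervals,
    read_pairs,
    slop,
    write_expression,
    write_genes,
    write_intervals,
    write_pairs,
)

# ---------------------------------------------------------------------------
# per-base oracle helpers
# ---------------------------------------------------------------------------

CHROM_LEN = 50_000


def coverage(intervals, length=CHROM_LEN):
    """Bit vector of covered bases for intervals on one chromosome."""
    bits = np.zeros(length, dtype=bool)
    for iv in intervals:
        bits[iv.start : min(iv.end, length)] = True
    return bits


def random_intervals(rng, n, length=CHROM_LEN, max_span=2_000, chrom="chr1"):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = s + int(rng.integers(1, max_span))
        out.append(GenomicInterval(chrom, s, min(e, length)))
    return out


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


def test_interval_invariants():
    with pytest.raises(DataError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(DataError):
        GenomicInterval("", 0, 10)
    with pytest.raises(DataError):
        GenomicInterval("chr1", 0, 10, strand="x")
    iv = GenomicInterval("chr1", 100, 200)
    assert len(iv) == 100 and iv.midpoint == 150


@pytest.mark.parametrize(
    "strand,tss,tes",
    [("+", 1000, 4999), ("-", 4999, 1000)],
)
def test_gene_tss_tes_strand_mirror(strand, tss, tes):
    g = GeneModel("chr1", strand, 1000, 5000, "g")
    assert g.tss == tss and g.tes == tes


def test_gene_rejects_strandless_and_bad_exons():
    with pytest.raises(DataError):
        GeneModel("chr1", ".", 0, 100, "g")
    with pytest.raises(DataError):
        GeneModel("chr1", "+", 100, 200, "g", exons=((50, 150),))
    with pytest.raises(DataError):
        GeneModel("chr1", "+", 0, 300, "g", exons=((100, 200), (50, 90)))


def test_promoter_terminator_windows():
    g = GeneModel("chr1", "+", 496_000, 600_000, "b")
    assert (g.promoter(1000).start, g.promoter(1000).end) == (495_000, 497_000)
    a = GeneModel("chr1", "+", 60_000, 102_000, "a")
    assert (a.terminator(5000).start, a.terminator(5000).end) == (97_000, 107_000)
    # minus strand mirrors: promoter at tx_end, terminator at tx_start
    m = GeneModel("chr1", "-", 60_000, 102_000, "m")
    assert (m.promoter(1000).start, m.promoter(1000).end) == (101_000, 103_000)
    assert (m.terminator(5000).start, m.terminator(5000).end) == (55_000, 65_000)


def test_tadset_rejects_nesting():
    with pytest.raises(DataError):
        TadSet([GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 100, 900)])
    # abutting is fine
    TadSet([GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 1000, 2000)])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def test_read_bed3_and_errors(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("# comment\ntrack name=x\nchr1\t100\t200\n")
    ps = read_intervals(p, "bed3")
    assert len(ps) == 1
    assert ps.intervals[0] == GenomicInterval("chr1", 100, 200)

    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t200\t100\n")
    with pytest.raises(ParseError, match="line 1"):
        read_intervals(bad, "bed3")
    with pytest.raises(Exception):
        read_intervals(p, "bedX")


def test_read_narrowpeak_signalvalue(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t200\tpk1\t0\t.\t7.5\t-1\t-1\t50\n")
    ps = read_intervals(p, "narrowPeak")
    assert ps.intervals[0].score == 7.5
    assert ps.intervals[0].name == "pk1"


def test_gzip_transparent(tmp_path):
    p = tmp_path / "a.bed.gz"
    with gzip.open(p, "wt") as fh:
        fh.write("chr1\t0\t50\n")
    assert len(read_intervals(p, "bed3")) == 1


def test_bedpe_canonical_order_and_interchrom(tmp_path):
    p = tmp_path / "l.bedpe"
    p.write_text(
        "chr1\t0\t10000\tchr1\t50000\t60000\n"
        "chr1\t50000\t60000\tchr1\t0\t10000\n"
        "chr1\t0\t10000\tchr2\t0\t10000\n"
    )
    ls = read_pairs(p)
    assert len(ls) == 3
    a, b = ls.loops[0], ls.loops[1]
    assert a.anchor1 == b.anchor1 and a.anchor2 == b.anchor2  # reversed input
    assert ls.loops[2].inter_chromosomal
    assert len(ls.intra_chromosomal()) == 2


def test_read_genes_bed6_and_bed12(tmp_path):
    p = tmp_path / "g.bed"
    p.write_text(
        "chr1\t1000\t5000\tgeneA\t0\t+\n"
        "chr1\t1000\t5000\tgeneB\t0\t-\n"
    )
    genes = read_genes(p)
    assert genes[0].tss == 1000 and genes[0].tes == 4999
    assert genes[1].tss == 4999 and genes[1].tes == 1000

    b12 = tmp_path / "g12.bed"
    b12.write_text(
        "chr1\t1000\t3100\tg\t0\t+\t1000\t3100\t0\t3\t100,100,100,\t0,1000,2000,\n"
    )
    (g,) = read_genes(b12)
    assert g.exons == ((1000, 1100), (2000, 2100), (3000, 3100))
    # per-base union of exons equals the expanded blocks
    bits = np.zeros(4000, dtype=bool)
    for s, e in g.exons:
        bits[s:e] = True
    assert bits.sum() == 300

    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t0\t100\tg\t0\t.\n")
    with pytest.raises(ParseError, match="strand"):
        read_genes(bad)


def test_read_expression_rules(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("gene_id\tTPM\ngA\t10.0\ngB\t0.0\n")
    t = read_expression(p)
    assert len(t) == 2 and t["gA"] == 10.0

    dup = tmp_path / "dup.tsv"
    dup.write_text("gene_id\tTPM\ngA\t1.0\ngA\t3.0\n")
    assert read_expression(dup)["gA"] == 3.0

    neg = tmp_path / "neg.tsv"
    neg.write_text("gene_id\tTPM\ngC\t-1\n")
    with pytest.raises(ParseError):
        read_expression(neg)


@pytest.mark.parametrize("fmt", ["bed3", "bed6", "narrowPeak"])
def test_interval_roundtrip(tmp_path, rng, fmt):
    ivs = random_intervals(rng, 50)
    if fmt != "bed3":
        ivs = [
            GenomicInterval(i.chrom, i.start, i.end, "+", f"p{k}", float(k))
            for k, i in enumerate(ivs)
        ]
    ps = PeakSet(ivs)
    path = tmp_path / f"x.{fmt}"
    write_intervals(ps, path, fmt)
    back = read_intervals(path, fmt)
    assert [(i.chrom, i.start, i.end) for i in back] == [
        (i.chrom, i.start, i.end) for i in ps
    ]
    if fmt != "bed3":
        assert [i.score for i in back] == [i.score for i in ps]
        assert [i.name for i in back] == [i.name for i in ps]


def test_genes_and_pairs_and_expression_roundtrip(tmp_path, default_dataset):
    ds = default_dataset
    gp = tmp_path / "genes.bed12"
    write_genes(ds.genes, gp)
    back = read_genes(gp)
    assert [(g.chrom, g.tx_start, g.tx_end, g.strand, g.gene_id, g.exons)
            for g in back] == [
        (g.chrom, g.tx_start, g.tx_end, g.strand, g.gene_id, g.exons)
        for g in ds.genes
    ]
    lp = tmp_path / "loops.bedpe"
    write_pairs(ds.loops, lp)
    back_loops = read_pairs(lp)
    assert [(l.anchor1, l.anchor2, l.name) for l in back_loops] == [
        (l.anchor1, l.anchor2, l.name) for l in ds.loops
    ]
    ep = tmp_path / "expr.tsv"
    write_expression(ds.expression, ep)
    back_expr = read_expression(ep)
    for gid, v in ds.expression.tpm.items():
        assert back_expr[gid] == pytest.approx(v, rel=1e-5)


# ---------------------------------------------------------------------------
# interval algebra vs per-base oracle
# ---------------------------------------------------------------------------


def test_slop_hand_examples():
    sizes = {"chr1": 10_000}
    out = slop(PeakSet([GenomicInterval("chr1", 1000, 1500)]), 1000, sizes)
    assert (out.intervals[0].start, out.intervals[0].end) == (0, 2500)
    out = slop(PeakSet([GenomicInterval("chr1", 9500, 9800)]), 1000, sizes)
    assert (out.intervals[0].start, out.intervals[0].end) == (8500, 10_000)
    ps = PeakSet([GenomicInterval("chr1", 4000, 4100)])
    assert slop(ps, 0, sizes) == ps
    with pytest.raises(DataError, match="chrMissing"):
        slop(PeakSet([GenomicInterval("chrMissing", 0, 10)]), 5, sizes)


def test_slop_composition_without_clipping(rng):
    sizes = {"chr1": 10 * CHROM_LEN}
    ivs = PeakSet(
        [GenomicInterval("chr1", s, s + 100) for s in
         rng.integers(5_000, 9 * CHROM_LEN, size=50)]
    )
    once = slop(slop(ivs, 700, sizes), 300, sizes)
    combined = slop(ivs, 1000, sizes)
    assert once == combined


def test_overlap_semantics_half_open():
    b = PeakSet([GenomicInterval("chr1", 150, 300)])
    assert overlaps_any(GenomicInterval("chr1", 100, 200), b)
    assert not overlaps_any(GenomicInterval("chr1", 100, 150), b)  # abutting
    assert not overlaps_any(GenomicInterval("chr2", 100, 200), b)


def test_filter_partition_counts(rng):
    a = PeakSet(random_intervals(rng, 200))
    b = PeakSet(random_intervals(rng, 50))
    keep = filter_nonoverlapping(a, b)
    dropped = [iv for iv in a if overlaps_any(iv, b)]
    assert len(keep) + len(dropped) == len(a)
    for iv in keep:
        assert not overlaps_any(iv, b)


def test_merge_union_length_equals_oracle(rng):
    ivs = random_intervals(rng, 500)
    merged = merge_intervals(PeakSet(ivs))
    oracle = coverage(ivs)
    assert sum(len(iv) for iv in merged) == int(oracle.sum())
    # disjoint and sorted
    prev_end = -1
    for iv in merged.intervals:
        assert iv.start > prev_end  # book-ended intervals were merged too
        prev_end = iv.end


@settings(max_examples=250, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_overlap_predicates_match_bitvector_oracle(seed):
    """Randomized slop/filter/overlap cases agree with the per-base oracle."""
    rng = np.random.default_rng(seed)
    a = random_intervals(rng, 20, max_span=3_000)
    b = random_intervals(rng, 10, max_span=3_000)
    b_set = PeakSet(b)
    cov_b = coverage(b)
    for iv in a:
        assert overlaps_any(iv, b_set) == bool(cov_b[iv.start : iv.end].any())
    flank = int(rng.integers(0, 2_000))
    sizes = {"chr1": CHROM_LEN}
    slopped = slop(b_set, flank, sizes)
    cov_slop = np.zeros(CHROM_LEN, dtype=bool)
    for iv in b:
        cov_slop[max(0, iv.start - flank) : min(CHROM_LEN, iv.end + flank)] = True
    assert np.array_equal(coverage(slopped), cov_slop)
    kept = filter_nonoverlapping(PeakSet(a), slopped)
    expected = [iv for iv in sorted(a) if not cov_slop[iv.start : iv.end].any()]
    assert [
        (i.chrom, i.start, i.end) for i in kept
    ] == [(i.chrom, i.start, i.end) for i in sorted(expected)]
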