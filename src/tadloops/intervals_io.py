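"""Genomic-interval data model, BED-family readers/writers, and interval algebra.

Coordinates are 0-based half-open (BED convention) throughout.  Overlap means
at least one shared base pair: two intervals that merely abut (``a.end ==
b.start``) do not overlap.  All readers transparently handle gzip (by ``.gz``
suffix) and skip ``track``/``browser``/``#`` lines.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed record in an input file (carries the 1-based line number)."""


class DataError(ValueError):
    """Semantically invalid data (bad coordinates, missing chromosome, ...)."""


class UsageError(ValueError):
    """Invalid arguments (unknown format token, bad parameter value)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a chromosome.

    Sort order is (chrom, start, end), which is the canonical order for
    every PeakSet.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval coordinates {self.chrom}:{self.start}-{self.end}"
                " (require 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Stranded transcript with optional exon structure and CDS bounds.

    ``exons`` defaults to a single exon spanning the transcript.  ``cds_start``
    / ``cds_end`` (half-open) are populated from BED12 thickStart/thickEnd when
    present; without them UTR annotation is unavailable.
    """

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    gene_id: str
    exons: tuple[tuple[int, int], ...] = ()
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(
                f"gene {self.gene_id}: strand must be '+' or '-' "
                "(TSS/TES are undefined without strand)"
            )
        if not (0 <= self.tx_start < self.tx_end):
            raise DataError(f"gene {self.gene_id}: invalid transcript span")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.tx_start, self.tx_end),))
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise DataError(f"gene {self.gene_id}: exon ({s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise DataError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (a single base position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcript end site (a single base position)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def promoter(self, flank: int = 1000) -> GenomicInterval:
        """TSS +/- flank window (centered on the transcript edge coordinate,
        floored at 0)."""
        center = self.tx_start if self.strand == "+" else self.tx_end
        return GenomicInterval(
            self.chrom, max(0, center - flank), center + flank,
            strand=self.strand, name=self.gene_id,
        )

    def terminator(self, flank: int = 5000) -> GenomicInterval:
        """TES +/- flank window (centered on the transcript edge coordinate,
        floored at 0)."""
        center = self.tx_end if self.strand == "+" else self.tx_start
        return GenomicInterval(
            self.chrom, max(0, center - flank), center + flank,
            strand=self.strand, name=self.gene_id,
        )

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.tx_start, self.tx_end, strand=self.strand,
            name=self.gene_id,
        )

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic coordinate order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


class PeakSet:
    """A named set of intervals kept in canonical (chrom, start) sort order.

    Raw peak calls may overlap each other; no merging is implied.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], mark: str | None = None):
        self.mark = mark
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._index: dict[str, tuple[list[int], list[int]]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        self._chrom_index(chrom)
        return self._chrom_ivs.get(chrom, [])

    def _build_index(self) -> None:
        self._chrom_ivs: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            self._chrom_ivs.setdefault(iv.chrom, []).append(iv)
        self._index = {}
        for chrom, ivs in self._chrom_ivs.items():
            starts = [iv.start for iv in ivs]
            # running max of ends allows binary-search pruning with nested peaks
            max_ends: list[int] = []
            m = 0
            for iv in ivs:
                m = max(m, iv.end)
                max_ends.append(m)
            self._index[chrom] = (starts, max_ends)

    def _chrom_index(self, chrom: str) -> tuple[list[int], list[int]]:
        if self._index is None:
            self._build_index()
        return self._index.get(chrom, ([], []))


@dataclass(frozen=True)
class Loop:
    """A paired-anchor chromatin interaction, anchors canonically ordered."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: float | None = None
    inter_chromosomal: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        a1, a2 = self.anchor1, self.anchor2
        if a1.chrom != a2.chrom:
            object.__setattr__(self, "inter_chromosomal", True)
        if (a1.chrom, a1.start, a1.end) > (a2.chrom, a2.start, a2.end):
            object.__setattr__(self, "anchor1", a2)
            object.__setattr__(self, "anchor2", a1)


class LoopSet:
    def __init__(self, loops: Iterable[Loop]):
        self.loops: list[Loop] = list(loops)

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self) -> Iterator[Loop]:
        return iter(self.loops)

    def intra_chromosomal(self) -> "LoopSet":
        return LoopSet(l for l in self.loops if not l.inter_chromosomal)


class TadSet:
    """Topological domains; per chromosome sorted, abutting allowed, nesting not."""

    def __init__(self, domains: Iterable[GenomicInterval]):
        self.domains: list[GenomicInterval] = sorted(
            domains, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        prev: GenomicInterval | None = None
        for d in self.domains:
            if prev is not None and d.chrom == prev.chrom and d.end <= prev.end:
                raise DataError(
                    f"nested TADs: {d.chrom}:{d.start}-{d.end} inside "
                    f"{prev.chrom}:{prev.start}-{prev.end}"
                )
            prev = d

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.domains)


class ExpressionTable:
    """gene_id -> TPM mapping; duplicate ids resolve to the maximum TPM."""

    def __init__(self, tpm: dict[str, float]):
        for gid, v in tpm.items():
            if v < 0:
                raise DataError(f"negative TPM for gene {gid}")
        self.tpm = dict(tpm)

    def __len__(self) -> int:
        return len(self.tpm)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.tpm

    def __getitem__(self, gene_id: str) -> float:
        return self.tpm[gene_id]

    def get(self, gene_id: str, default: float | None = None) -> float | None:
        return self.tpm.get(gene_id, default)


ChromSizes = dict  # chromosome name -> length in bp


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _records(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what} {token!r}") from None


def _parse_interval_fields(
    fields: Sequence[str], lineno: int
) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: expected >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    start = _parse_int(fields[1], "start", lineno)
    end = _parse_int(fields[2], "end", lineno)
    if start >= end or start < 0:
        raise ParseError(
            f"line {lineno}: invalid coordinates {chrom}:{start}-{end}"
        )
    return chrom, start, end


def read_intervals(path: str | Path, format: str = "bed6", mark: str | None = None) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a :class:`PeakSet`.

    narrowPeak signalValue (column 7) is stored as the interval score; the
    summit column is parsed for validity but not retained.
    """
    if format not in ("bed3", "bed6", "narrowPeak"):
        raise UsageError(f"unknown interval format {format!r}")
    min_cols = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[format]
    out = []
    for lineno, f in _records(path):
        if len(f) < min_cols:
            raise ParseError(
                f"line {lineno}: {format} requires >= {min_cols} columns, got {len(f)}"
            )
        chrom, start, end = _parse_interval_fields(f, lineno)
        name = None
        strand = "."
        score: float | None = None
        if format in ("bed6", "narrowPeak"):
            name = f[3] if f[3] != "." else None
            strand = f[5] if f[5] in VALID_STRANDS else "."
        if format == "bed6":
            try:
                score = float(f[4])
            except ValueError:
                score = None
        elif format == "narrowPeak":
            try:
                score = float(f[6])  # signalValue
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric signalValue {f[6]!r}")
            _parse_int(f[9], "summit offset", lineno)  # validated, unused
        out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return PeakSet(out, mark=mark)


def write_intervals(peaks: PeakSet, path: str | Path, format: str = "bed6") -> None:
    if format not in ("bed3", "bed6", "narrowPeak"):
        raise UsageError(f"unknown interval format {format!r}")
    with open(path, "wt") as fh:
        for iv in peaks:
            if format == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif format == "bed6":
                score = 0.0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{score:g}\t{iv.strand}\n"
                )
            else:  # narrowPeak: signalValue in col 7, placeholder p/q, summit -1
                sig = 0.0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0"
                    f"\t{iv.strand}\t{sig:g}\t-1\t-1\t-1\n"
                )


def read_pairs(path: str | Path, format: str = "bedpe") -> LoopSet:
    """Read a BEDPE file (>= 6 columns).  Anchors are canonically ordered;
    inter-chromosomal records are retained and flagged."""
    if format != "bedpe":
        raise UsageError(f"unknown pair format {format!r}")
    loops = []
    for lineno, f in _records(path):
        if len(f) < 6:
            raise ParseError(f"line {lineno}: BEDPE requires >= 6 columns")
        c1, s1, e1 = _parse_interval_fields(f[0:3], lineno)
        c2, s2, e2 = _parse_interval_fields(f[3:6], lineno)
        name = f[6] if len(f) > 6 and f[6] != "." else None
        score = None
        if len(f) > 7:
            try:
                score = float(f[7])
            except ValueError:
                score = None
        loops.append(
            Loop(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2),
                 score=score, name=name)
        )
    return LoopSet(loops)


def write_pairs(loops: LoopSet, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{lp.name or '.'}\t{lp.score if lp.score is not None else '.'}\n"
            )


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (single-exon) or BED12 (exon blocks).

    BED12 thickStart/thickEnd define CDS bounds; equal values mean no CDS.
    Strandless records are rejected because TSS/TES are undefined.
    """
    genes = []
    for lineno, f in _records(path):
        if len(f) < 6:
            raise ParseError(f"line {lineno}: gene records require >= 6 columns")
        chrom, start, end = _parse_interval_fields(f, lineno)
        gene_id = f[3]
        strand = f[5]
        if strand not in ("+", "-"):
            raise ParseError(
                f"line {lineno}: gene {gene_id!r} has strand {strand!r}; "
                "stranded genes are required to define TSS/TES"
            )
        exons: tuple[tuple[int, int], ...] = ()
        cds_start = cds_end = None
        if len(f) >= 12:
            thick_start = _parse_int(f[6], "thickStart", lineno)
            thick_end = _parse_int(f[7], "thickEnd", lineno)
            if thick_end > thick_start:
                cds_start, cds_end = thick_start, thick_end
            n_blocks = _parse_int(f[9], "blockCount", lineno)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(
                    f"line {lineno}: blockCount {n_blocks} does not match "
                    f"{len(sizes)} sizes / {len(offsets)} starts"
                )
            exons = tuple(
                (start + off, start + off + sz) for off, sz in zip(offsets, sizes)
            )
        genes.append(
            GeneModel(chrom, strand, start, end, gene_id, exons, cds_start, cds_end)
        )
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12."""
    with open(path, "wt") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
            cs = g.cds_start if g.cds_start is not None else g.tx_start
            ce = g.cds_end if g.cds_end is not None else g.tx_start
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{cs}\t{ce}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_expression(
    path: str | Path, gene_col: str = "gene_id", tpm_col: str = "TPM"
) -> ExpressionTable:
    """Read a TSV expression quantification (gene id + TPM columns).

    Duplicate gene ids keep the maximum TPM (logged); negative TPM is an error.
    """
    tpm: dict[str, float] = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            gi, ti = header.index(gene_col), header.index(tpm_col)
        except ValueError:
            raise ParseError(
                f"expression header lacks columns {gene_col!r}/{tpm_col!r}: {header}"
            ) from None
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) <= max(gi, ti):
                raise ParseError(f"line {lineno}: too few columns")
            gid = f[gi]
            try:
                val = float(f[ti])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric TPM {f[ti]!r}") from None
            if val < 0:
                raise ParseError(f"line {lineno}: negative TPM {val} for {gid}")
            if gid in tpm:
                logger.warning("duplicate gene id %s: keeping max TPM", gid)
                val = max(val, tpm[gid])
            tpm[gid] = val
    return ExpressionTable(tpm)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\tTPM\n")
        for gid in sorted(table.tpm):
            fh.write(f"{gid}\t{table.tpm[gid]:.6g}\n")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    sizes: ChromSizes = {}
    for lineno, f in _records(path):
        if len(f) < 2:
            raise ParseError(f"line {lineno}: chrom.sizes requires 2 columns")
        length = _parse_int(f[1], "chromosome length", lineno)
        if length <= 0:
            raise ParseError(f"line {lineno}: non-positive length {length}")
        sizes[f[0]] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph track into (chrom, start, end, value) tuples, sorted."""
    out = []
    for lineno, f in _records(path):
        if len(f) < 4:
            raise ParseError(f"line {lineno}: bedGraph requires 4 columns")
        chrom, start, end = _parse_interval_fields(f, lineno)
        try:
            value = float(f[3])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric value {f[3]!r}") from None
        out.append((chrom, start, end, value))
    out.sort(key=lambda r: (r[0], r[1]))
    return out


def write_bedgraph(track: Sequence[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for chrom, start, end, value in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def slop(peaks: PeakSet, flank: int, sizes: ChromSizes) -> PeakSet:
    """Extend every interval by ``flank`` bp on both sides, clipped to the
    chromosome (bedtools-slop semantics).  Interval count is preserved."""
    if flank < 0:
        raise UsageError("flank must be >= 0")
    out = []
    for iv in peaks:
        if iv.chrom not in sizes:
            raise DataError(f"chromosome {iv.chrom!r} missing from chrom sizes")
        length = sizes[iv.chrom]
        out.append(
            replace(iv, start=max(0, iv.start - flank), end=min(length, iv.end + flank))
        )
    return PeakSet(out, mark=peaks.mark)


def overlaps_any(a: GenomicInterval, b_set: PeakSet) -> bool:
    """True iff ``a`` shares >= 1 bp with any interval of ``b_set``."""
    starts, max_ends = b_set._chrom_index(a.chrom)
    if not starts:
        return False
    # candidates: intervals with start < a.end whose running-max end > a.start
    hi = bisect_left(starts, a.end)
    if hi == 0:
        return False
    # walk back while the running max end can still reach past a.start
    lo = bisect_right(max_ends, a.start, 0, hi)
    ivs = b_set._chrom_ivs[a.chrom]
    for i in range(lo, hi):
        if ivs[i].end > a.start:
            return True
    return False


def filter_nonoverlapping(a: PeakSet, b: PeakSet) -> PeakSet:
    """Whole intervals of ``a`` that overlap nothing in ``b`` (never truncated)."""
    return PeakSet(
        (iv for iv in a if not overlaps_any(iv, b)), mark=a.mark
    )


def merge_intervals(a: PeakSet) -> PeakSet:
    """Union overlapping or book-ended intervals per chromosome; output is
    disjoint and sorted.  Strand/name/score are dropped on merged output."""
    out: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in a:  # already canonically sorted
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
        else:
            if cur is not None:
                out.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(cur)
    return PeakSet(out, mark=a.mark)
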