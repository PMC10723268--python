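"""Contact-matrix operations: ingestion, VC_SQRT balancing, virtual 4C, APA.

Matrices are symmetric, intra-chromosomal, densely stored at a fixed bin
resolution and interchanged as plain-text COO triples (bin_i, bin_j, count)
with ``bin_i <= bin_j``.  VC_SQRT divides each entry by the square roots of
its row and column coverage.  Virtual 4C extracts the (averaged) viewpoint
rows.  Aggregate peak analysis (APA) averages fixed-size windows centered on
loop pixels and summarizes enrichment as center over lower-left-corner mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals_io import DataError, GenomicInterval, LoopSet, UsageError


@dataclass
class ContactMatrix:
    chrom: str
    resolution: int
    matrix: np.ndarray
    normalized: str | None = None  # normalization method name, None = raw
    zero_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DataError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise DataError("contact matrix must be symmetric")
        if (m < 0).any():
            raise DataError("contact matrix entries must be non-negative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, position: int) -> int:
        b = position // self.resolution
        if not (0 <= b < self.n_bins):
            raise DataError(
                f"position {position} outside matrix span of {self.chrom}"
            )
        return b


@dataclass
class ApaResult:
    aggregate: np.ndarray
    n_loops_used: int
    n_loops_skipped: int
    skip_reasons: dict[str, int]
    score: float


def load_matrix(
    path: str | Path, resolution: int, chrom: str, n_bins: int
) -> ContactMatrix:
    """Load COO triples (bin_i, bin_j, count), ``bin_i <= bin_j``, into a
    symmetric dense matrix; missing pairs are 0.  Duplicate mirror entries
    with conflicting counts are an error."""
    m = np.zeros((n_bins, n_bins))
    seen: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise DataError(f"line {lineno}: expected 3 columns")
            try:
                i, j, c = int(f[0]), int(f[1]), float(f[2])
            except ValueError:
                raise DataError(f"line {lineno}: malformed COO record") from None
            if i > j:
                i, j = j, i
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise DataError(f"line {lineno}: bin index out of range")
            key = (i, j)
            if key in seen and seen[key] != c:
                raise DataError(
                    f"line {lineno}: conflicting duplicate entry for bins {key}"
                )
            seen[key] = c
            m[i, j] = c
            m[j, i] = c
    return ContactMatrix(chrom, resolution, m)


def write_matrix(cm: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (including diagonal) as COO triples,
    omitting zeros."""
    with open(path, "wt") as fh:
        iu, ju = np.nonzero(np.triu(cm.matrix))
        for i, j in zip(iu, ju):
            v = cm.matrix[i, j]
            fh.write(f"{i}\t{j}\t{v:g}\n")


def vc_sqrt_normalize(cm: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage balancing.

    Each entry is divided by sqrt(row sum) * sqrt(column sum); zero-coverage
    rows are left zero and flagged.  The result is rescaled by one constant
    so the mean of its nonzero entries matches the raw matrix's.
    """
    m = cm.matrix
    if not m.any():
        raise DataError("cannot normalize an all-zero matrix")
    r = m.sum(axis=1)
    zero = r == 0
    s = np.where(zero, 1.0, np.sqrt(r))
    out = m / np.outer(s, s)
    out[zero, :] = 0.0
    out[:, zero] = 0.0
    nz_raw = m[m > 0]
    nz_out = out[out > 0]
    out *= nz_raw.mean() / nz_out.mean()
    return ContactMatrix(cm.chrom, cm.resolution, out, normalized="VC_SQRT",
                         zero_rows=np.flatnonzero(zero))


def virtual_4c(
    cm: ContactMatrix, anchor: GenomicInterval
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-all interaction profile of a viewpoint anchor.

    Returns (bin_start_coordinates, profile) where profile_b is the mean over
    the anchor's bins a of matrix[a, b].
    """
    if anchor.chrom != cm.chrom:
        raise DataError(
            f"anchor on {anchor.chrom} but matrix is for {cm.chrom}"
        )
    first = anchor.start // cm.resolution
    last = (anchor.end - 1) // cm.resolution
    if last < 0 or first >= cm.n_bins:
        raise DataError("anchor outside matrix span")
    first, last = max(0, first), min(cm.n_bins - 1, last)
    profile = cm.matrix[first : last + 1, :].mean(axis=0)
    coords = np.arange(cm.n_bins) * cm.resolution
    return coords, profile


def apa(
    cm: ContactMatrix,
    loops: LoopSet,
    window: int = 6,
    corner_size: int = 3,
) -> ApaResult:
    """Aggregate peak analysis over loop pixels.

    For each intra-chromosomal loop on the matrix chromosome, the pixel is
    (anchor1-midpoint bin i, anchor2-midpoint bin j), i < j.  Loops too near
    the diagonal (j - i <= 2*window, whose window would cross it) or whose
    (2w+1)^2 window leaves the matrix are skipped and counted.  The aggregate
    is the element-wise mean of surviving windows with row/column index
    increasing with genomic coordinate; the score divides the center pixel by
    the mean of the ``corner_size``-square block at the lower-left corner
    (high row index, low column index — the highest-background corner, so
    the score is conservative).
    """
    if window < 1:
        raise UsageError("window must be >= 1")
    if not (1 <= corner_size <= window):
        raise UsageError("corner_size must be in [1, window]")
    w = window
    size = 2 * w + 1
    agg = np.zeros((size, size))
    used = 0
    skips: dict[str, int] = {}

    def skip(reason: str) -> None:
        skips[reason] = skips.get(reason, 0) + 1

    for lp in loops:
        if lp.inter_chromosomal or lp.anchor1.chrom != cm.chrom:
            skip("off-chromosome")
            continue
        i = lp.anchor1.midpoint // cm.resolution
        j = lp.anchor2.midpoint // cm.resolution
        if i > j:
            i, j = j, i
        if j - i <= 2 * w:
            skip("too close to diagonal")
            continue
        if i - w < 0 or j + w >= cm.n_bins or j - w < 0 or i + w >= cm.n_bins:
            skip("window outside matrix")
            continue
        agg += cm.matrix[i - w : i + w + 1, j - w : j + w + 1]
        used += 1
    if used == 0:
        raise DataError(f"no loops usable for APA; skips: {skips}")
    agg /= used
    corner = agg[size - corner_size : size, 0:corner_size]
    corner_mean = corner.mean()
    center = agg[w, w]
    score = float(center / corner_mean) if corner_mean > 0 else float("inf")
    return ApaResult(agg, used, sum(skips.values()), skips, score)
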