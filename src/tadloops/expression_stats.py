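"""Expression grouping and rank-based two-/k-sample tests.

Gene groups defined by chromatin context (H3K27me3-marked vs unmarked
promoters looped to p300-only peaks; PT/PG/PP boundary-pair categories) are
compared on the log2(TPM+1) scale with a self-contained Mann-Whitney
rank-sum test (midranks, tie-corrected normal approximation with continuity
correction, exact enumeration for small tie-free samples) and a
Kruskal-Wallis test with tie correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2, norm

from .intervals_io import DataError, ExpressionTable, GeneModel, PeakSet, UsageError

logger = logging.getLogger(__name__)


@dataclass
class GroupedExpression:
    """Per-group log2(TPM+1) values with gene-id provenance."""

    values: dict[str, list[float]]
    gene_ids: dict[str, list[str]]


@dataclass
class TestReport:
    grouping: str
    group_sizes: dict[str, int]
    medians: dict[str, float]
    statistic: float
    statistic_name: str
    p_value: float


def log2_transform(tpm: float) -> float:
    """log2(TPM + 1); the expression scale used for all comparisons."""
    if tpm < 0:
        raise DataError(f"negative TPM {tpm}")
    return math.log2(tpm + 1.0)


def ecdf(values: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted unique breakpoints x and
    cumulative fractions F(x) = P(X <= x); F(max) = 1."""
    if len(values) == 0:
        raise DataError("ECDF of an empty sample is undefined")
    x = np.sort(np.asarray(values, dtype=float))
    xs, counts = np.unique(x, return_counts=True)
    return xs, np.cumsum(counts) / len(x)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their rank range."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_test(
    x: list[float] | np.ndarray, y: list[float] | np.ndarray
) -> tuple[float, float, float]:
    """Mann-Whitney U test (two-sided). Returns (U, z, p).

    U counts pairs where an x observation exceeds a y observation (ties
    count one half).  Tie-free samples with nx + ny <= 10 use exact
    enumeration of all label arrangements; otherwise the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.  z is reported from the approximation in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise UsageError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2  # = #{x_i > y_j} + 0.5 #ties
    mean_u = nx * ny / 2
    n = nx + ny
    tie = _tie_term(pooled)
    var_u = nx * ny / 12 * ((n + 1) - tie / (n * (n - 1))) if n > 1 else 0.0
    if var_u > 0:
        z = (u - mean_u - math.copysign(0.5, u - mean_u)) / math.sqrt(var_u)
        if u == mean_u:
            z = 0.0
    else:
        z = 0.0

    no_ties = len(np.unique(pooled)) == n
    if n <= 10 and no_ties:
        p = _exact_two_sided_p(ranks, nx, u)
    else:
        p = min(1.0, 2 * norm.sf(abs(z)))
    return u, z, p


def _exact_two_sided_p(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of the C(n, nx) label
    arrangements of the pooled ranks: P(|U - U_mean| >= |u_obs - U_mean|)."""
    n = len(ranks)
    ny = n - nx
    mean_u = nx * ny / 2
    dev = abs(u_obs - mean_u)
    hits = total = 0
    offset = nx * (nx + 1) / 2
    for combo in combinations(range(n), nx):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    if len(groups) < 2:
        raise UsageError("kruskal_wallis requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise UsageError("kruskal_wallis requires non-empty groups")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    i = 0
    for a in arrays:
        r = ranks[i : i + len(a)].sum()
        h += r * r / len(a)
        i += len(a)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1 - _tie_term(pooled) / (n**3 - n)
    if correction > 0:
        h /= correction
    p = float(chi2.sf(h, df=len(groups) - 1))
    return h, p


def group_by_h3k27me3(
    loop_annotations,
    genes: list[GeneModel],
    h3k27me3: PeakSet,
    expression: ExpressionTable,
    promoter_flank: int = 1000,
) -> GroupedExpression:
    """Genes looped to p300-only peaks, split by promoter H3K27me3 overlap.

    For every annotated loop with a p300-only mark on one anchor, genes whose
    promoter window intersects the partner anchor are collected; each gene is
    assigned to "H3K27me3" if its promoter overlaps an H3K27me3 peak, else
    "nonH3K27me3".  Genes missing from the expression table are dropped with
    a log line.
    """
    gene_by_id = {}
    for g in genes:
        gene_by_id.setdefault(g.gene_id, []).append(g)
    assigned: dict[str, str] = {}
    for a1, a2 in loop_annotations:
        for marked, partner in ((a1, a2), (a2, a1)):
            if not marked.has_p300_only:
                continue
            for g in genes:
                if g.chrom != partner.anchor.chrom:
                    continue
                prom = g.promoter(promoter_flank)
                if not partner.anchor.overlaps(prom):
                    continue
                from .intervals_io import overlaps_any

                label = (
                    "H3K27me3" if overlaps_any(prom, h3k27me3) else "nonH3K27me3"
                )
                # a gene marked repressed anywhere stays repressed
                if assigned.get(g.gene_id) != "H3K27me3":
                    assigned[g.gene_id] = label
    values: dict[str, list[float]] = {"H3K27me3": [], "nonH3K27me3": []}
    ids: dict[str, list[str]] = {"H3K27me3": [], "nonH3K27me3": []}
    for gid, label in sorted(assigned.items()):
        if gid not in expression:
            logger.info("gene %s absent from expression table; dropped", gid)
            continue
        values[label].append(log2_transform(expression[gid]))
        ids[label].append(gid)
    return GroupedExpression(values, ids)


def group_by_boundary_category(
    boundary_features,
    expression: ExpressionTable,
    categories: tuple[str, ...] = ("PP", "PT", "PG"),
) -> GroupedExpression:
    """Per-boundary gene expression collected under the TAD pair's category.

    Each (TAD, boundary) occurrence contributes its genes separately, so a
    gene anchoring several qualifying TADs is counted once per occurrence.
    """
    values: dict[str, list[float]] = {c: [] for c in categories}
    ids: dict[str, list[str]] = {c: [] for c in categories}
    for bf in boundary_features:
        cat = bf.pair_category
        if cat not in categories:
            continue
        for gid in bf.left_genes + bf.right_genes:
            if gid not in expression:
                logger.info("gene %s absent from expression table; dropped", gid)
                continue
            values[cat].append(log2_transform(expression[gid]))
            ids[cat].append(gid)
    return GroupedExpression(values, ids)


def compare_groups(grouped: GroupedExpression, grouping: str) -> TestReport:
    """Two-group Wilcoxon/Mann-Whitney or k-group Kruskal-Wallis report."""
    nonempty = {k: v for k, v in grouped.values.items() if v}
    empty = [k for k, v in grouped.values.items() if not v]
    if empty:
        raise DataError(f"empty group(s) after filtering: {', '.join(empty)}")
    labels = list(nonempty)
    sizes = {k: len(v) for k, v in nonempty.items()}
    medians = {k: float(np.median(v)) for k, v in nonempty.items()}
    if len(labels) == 2:
        u, _, p = rank_sum_test(nonempty[labels[0]], nonempty[labels[1]])
        return TestReport(grouping, sizes, medians, u, "U", p)
    h, p = kruskal_wallis([nonempty[k] for k in labels])
    return TestReport(grouping, sizes, medians, h, "H", p)
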