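"""Rank-based tests, ECDF, and expression grouping.

scipy.stats serves as the independent oracle for the self-contained
Mann-Whitney / Kruskal-Wallis implementations; tiny samples are additionally
checked against full permutation enumeration.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import mannwhitneyu, norm

from tadloops.intervals_io import DataError, UsageError
from tadloops.expression_stats import (
    compare_groups,
    ecdf,
    GroupedExpression,
    group_by_h3k27me3,
    kruskal_wallis,
    log2_transform,
    rank_sum_test,
)
from tadloops import synthetic_data as sd
from tadloops.pipeline import fig5_loop_analysis


@pytest.mark.parametrize("tpm,expected", [(0, 0), (1, 1), (3, 2)])
def test_log2_transform(tpm, expected):
    assert log2_transform(tpm) == pytest.approx(expected)


def test_log2_transform_rejects_negative():
    with pytest.raises(DataError):
        log2_transform(-0.5)


def test_ecdf_definition(rng):
    xs, fs = ecdf([1.0, 2.0, 3.0])
    assert fs[np.searchsorted(xs, 2.0)] == pytest.approx(2 / 3)
    assert fs[-1] == 1.0
    values = rng.normal(size=100)
    xs, fs = ecdf(list(values))
    for probe in rng.choice(values, size=20, replace=False):
        idx = np.searchsorted(xs, probe)
        assert fs[idx] == pytest.approx((values <= probe).mean())
    # monotone, range [0, 1]
    assert (np.diff(fs) >= 0).all() and fs[0] > 0
    with pytest.raises(DataError):
        ecdf([])


def test_rank_sum_exact_small_sample():
    u, z, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
    assert u == 0
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_rank_sum_identical_samples():
    x = [1.0, 2.0, 2.0, 5.0]
    u, z, p = rank_sum_test(x, list(x))
    assert u == pytest.approx(len(x) ** 2 / 2)
    assert p == pytest.approx(1.0)


def test_rank_sum_requires_nonempty():
    with pytest.raises(UsageError):
        rank_sum_test([], [1.0])


def test_rank_sum_matches_scipy_with_ties(rng):
    for _ in range(100):
        x = rng.integers(0, 6, size=int(rng.integers(11, 40))).astype(float)
        y = rng.integers(0, 6, size=int(rng.integers(11, 40))).astype(float)
        u, _, p = rank_sum_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_rank_sum_exact_path_equals_enumeration():
    """All tie-free splits with pooled n <= 8 agree with full enumeration."""
    for n in range(2, 9):
        for nx in range(1, n):
            vals = np.arange(1.0, n + 1)
            for combo in itertools.combinations(range(n), nx):
                x = vals[list(combo)]
                y = np.delete(vals, list(combo))
                u, z, p = rank_sum_test(x, y)
                mean_u = nx * (n - nx) / 2
                obs = abs(u - mean_u)
                hits = total = 0
                for c2 in itertools.combinations(range(n), nx):
                    xx = vals[list(c2)]
                    yy = np.delete(vals, list(c2))
                    uu = sum(xi > yj for xi in xx for yj in yy)
                    total += 1
                    hits += abs(uu - mean_u) >= obs - 1e-12
                assert p == pytest.approx(hits / total, abs=1e-12)


def test_rank_sum_asymptotic_monotone_and_balanced_tail():
    """The normal-approximation p decreases as U departs from its mean, and
    agrees with the exact tail within 0.02 for the balanced 4+4 split."""
    nx = ny = 4
    vals = np.arange(1.0, 9.0)
    by_u = {}
    for combo in itertools.combinations(range(8), nx):
        x = vals[list(combo)]
        y = np.delete(vals, list(combo))
        u, z, p_exact = rank_sum_test(x, y)
        p_norm = min(1.0, 2 * norm.sf(abs(z)))
        by_u[u] = (p_norm, p_exact)
    mean_u = nx * ny / 2
    devs = sorted({abs(u - mean_u) for u in by_u})
    ps = [by_u[mean_u + d][0] if mean_u + d in by_u else by_u[mean_u - d][0]
          for d in devs]
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
    for u, (p_norm, p_exact) in by_u.items():
        if p_exact <= 0.1:  # the rejection-region tail
            assert abs(p_norm - p_exact) <= 0.02


def test_rank_sum_p_monotone_in_shift(rng):
    x = rng.normal(size=50)
    noise = rng.normal(size=50)
    ps = []
    for shift in [0.0, 0.3, 0.6, 1.0, 1.5]:
        _, _, p = rank_sum_test(x, noise + shift)
        ps.append(p)
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_kruskal_identical_groups():
    h, p = kruskal_wallis([[1.0, 2.0, 3.0]] * 3)
    assert h == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_kruskal_two_groups_equals_z_squared(rng):
    """For two groups, H equals the squared rank-sum z without continuity
    correction (asymptotic identity)."""
    x = rng.normal(size=20)
    y = rng.normal(size=25) + 0.5
    h, _ = kruskal_wallis([list(x), list(y)])
    u, _, _ = rank_sum_test(x, y)
    nx, ny = len(x), len(y)
    n = nx + ny
    var_u = nx * ny * (n + 1) / 12  # tie-free
    z_nocc = (u - nx * ny / 2) / math.sqrt(var_u)
    assert h == pytest.approx(z_nocc**2, abs=1e-9)


def test_kruskal_matches_scipy(rng):
    for _ in range(50):
        groups = [
            list(rng.integers(0, 10, size=int(rng.integers(5, 20))).astype(float))
            for _ in range(3)
        ]
        h, p = kruskal_wallis(groups)
        ref = scipy_kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)
    with pytest.raises(UsageError):
        kruskal_wallis([[1.0]])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rank_statistics_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=15)
    y = rng.normal(size=12)
    u1, _, p1 = rank_sum_test(x, y)
    f = lambda v: np.exp(3 * v) + 1  # strictly increasing
    u2, _, p2 = rank_sum_test(f(x), f(y))
    assert u1 == pytest.approx(u2) and p1 == pytest.approx(p2)
    h1, _ = kruskal_wallis([list(x), list(y)])
    h2, _ = kruskal_wallis([list(f(x)), list(f(y))])
    assert h1 == pytest.approx(h2)


def test_compare_groups_recovers_planted_deficit(default_dataset):
    """Genes with planted promoter H3K27me3 are expressed lower (delta=1)."""
    ds = default_dataset
    rep = fig5_loop_analysis(
        ds.loops, ds.genes, ds.peaks["p300"], ds.peaks["h3k27ac"],
        ds.peaks["h3k27me3"], ds.chrom_sizes, ds.expression,
    ).expression_report
    assert rep is not None
    assert rep.medians["H3K27me3"] < rep.medians["nonH3K27me3"]
    # groups match the planted gene labels
    truth = ds.ground_truth.gene_group
    assert rep.group_sizes["H3K27me3"] == \
        sum(1 for v in truth.values() if v == "repressed")


def test_compare_groups_drops_missing_and_errors_on_empty():
    grouped = GroupedExpression({"a": [1.0, 2.0], "b": []}, {"a": ["g1", "g2"], "b": []})
    with pytest.raises(DataError, match="b"):
        compare_groups(grouped, "x")


def test_missing_expression_ids_are_dropped(default_dataset):
    ds = default_dataset
    from tadloops.intervals_io import ExpressionTable
    from tadloops import anchor_interactions as ai
    from tadloops.peak_classes import derive_p300_only

    po = derive_p300_only(ds.peaks["p300"], ds.peaks["h3k27ac"], ds.chrom_sizes)
    anns = ai.annotate_loops(ds.loops, ds.genes, po, ds.peaks["h3k27me3"])
    full = group_by_h3k27me3(anns, ds.genes, ds.peaks["h3k27me3"], ds.expression)
    # remove one repressed gene from the table
    victim = full.gene_ids["H3K27me3"][0]
    reduced_tpm = {k: v for k, v in ds.expression.tpm.items() if k != victim}
    reduced = group_by_h3k27me3(
        anns, ds.genes, ds.peaks["h3k27me3"], ExpressionTable(reduced_tpm)
    )
    assert len(reduced.values["H3K27me3"]) == len(full.values["H3K27me3"]) - 1
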