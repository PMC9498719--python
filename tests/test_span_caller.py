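"""Span computation, Tukey-fence thresholds, classification, clustering.

The worked numbers: a span sample with quartiles 5,700/6,300 bp must give
fences at exactly 4,800 and 7,200 bp, and a 5-pair deletion cluster with
mean span 854,712 bp over a 6,000 bp-median library must size the deletion
at 848,712 bp.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allseq.formats_io import AlignedPair, ReadAln, SVType
from allseq.span_caller import (
    CallerConfig,
    InsufficientSpansError,
    LibrarySummary,
    LocusClass,
    MatePair,
    MPClass,
    SpanStats,
    classify_pair,
    cluster_calls,
    cluster_intervals,
    compute_spans,
    fit_span_thresholds,
    summarize_library,
    translocation_table,
)

# ---------------------------------------------------------------------------
# Spans
# ---------------------------------------------------------------------------


def _pair(pid, c1, s1, e1, c2, s2, e2):
    return AlignedPair(pid, ReadAln(c1, s1, e1, "+"), ReadAln(c2, s2, e2, "-"))


def test_intra_span_is_inclusive_outer_distance():
    res = compute_spans([_pair("p", "chr1", 100, 249, "chr1", 5950, 6099)])
    mp = res.mate_pairs[0]
    assert mp.span == 6000
    assert mp.locus_class is LocusClass.INTRA
    assert (mp.left_read_end, mp.right_read_start) == (249, 5950)
    assert (res.n_intra, res.n_inter) == (1, 0)


def test_inter_pair_has_no_span():
    res = compute_spans([_pair("p", "chr1", 100, 249, "chr2", 500, 649)])
    assert res.mate_pairs[0].span is None
    assert res.mate_pairs[0].locus_class is LocusClass.INTER
    assert (res.n_intra, res.n_inter) == (0, 1)
    assert len(translocation_table(res.mate_pairs)) == 1


def test_overlapping_mates_degenerate_span():
    res = compute_spans([_pair("p", "chr1", 100, 249, "chr1", 150, 299)])
    assert res.mate_pairs[0].span == 200  # outer 100..299


def test_mate_order_does_not_matter():
    a = compute_spans([_pair("p", "chr1", 5950, 6099, "chr1", 100, 249)])
    assert a.mate_pairs[0].span == 6000
    assert a.mate_pairs[0].outer_start == 100


# ---------------------------------------------------------------------------
# Threshold fitting
# ---------------------------------------------------------------------------


def quartile_oracle(values, q):
    """Independent linear-interpolation quartile on the sorted sample."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def test_published_fences_from_quartiles():
    stats = fit_span_thresholds([5700, 5700, 6000, 6300, 6300])
    assert stats.q1 == 5700 and stats.q3 == 6300 and stats.iqr == 600
    assert stats.lower_threshold == 4800
    assert stats.upper_threshold == 7200


def test_zero_iqr_degenerate():
    stats = fit_span_thresholds([6000] * 10)
    assert stats.iqr == 0
    assert (stats.lower_threshold, stats.upper_threshold) == (6000, 6000)


def test_fences_match_quartile_oracle_on_uniform_grid():
    spans = list(range(5000, 7001))
    stats = fit_span_thresholds(spans)
    q1, q3 = quartile_oracle(spans, 0.25), quartile_oracle(spans, 0.75)
    assert stats.q1 == pytest.approx(q1)
    assert stats.q3 == pytest.approx(q3)
    assert stats.lower_threshold == pytest.approx(q1 - 1.5 * (q3 - q1))
    assert stats.upper_threshold == pytest.approx(q3 + 1.5 * (q3 - q1))


def test_insufficient_spans():
    with pytest.raises(InsufficientSpansError):
        fit_span_thresholds([6000, 6100, 5900])


@given(st.lists(st.integers(1000, 10_000), min_size=4, max_size=200))
def test_threshold_identity_property(spans):
    """upper - lower = 4*IQR for every fitted sample."""
    stats = fit_span_thresholds(spans)
    assert stats.upper_threshold - stats.lower_threshold == pytest.approx(4 * stats.iqr)
    assert stats.q1 <= stats.median <= stats.q3
    assert stats.q1 == pytest.approx(quartile_oracle(spans, 0.25))


def test_fixed_threshold_mode_inverts_to_published_quartiles():
    stats = SpanStats.from_thresholds(4800, 7200)
    assert (stats.q1, stats.q3, stats.iqr, stats.median) == (5700, 6300, 600, 6000)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

STATS = SpanStats.from_thresholds(4800, 7200)


def _mp(span, chrom="chr1", start=1000):
    if span is None:
        return MatePair("x", chrom, "chr9", start, start + 149, start + 149,
                        500, None, LocusClass.INTER)
    return MatePair("x", chrom, chrom, start, start + span - 1,
                    start + 149, start + span - 150, span, LocusClass.INTRA)


@pytest.mark.parametrize(
    "span,expected",
    [
        (7300, MPClass.DELETION_SUPPORT),
        (4700, MPClass.INSERTION_SUPPORT),
        (7200, MPClass.NORMAL),  # fence value is normal
        (4800, MPClass.NORMAL),
        (6000, MPClass.NORMAL),
        (None, MPClass.INTERCHROM),
    ],
)
def test_classification_boundaries(span, expected):
    assert classify_pair(_mp(span), STATS) is expected


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def brute_force_single_linkage(intervals, window):
    """Union-find closure over the all-pairs linkage predicate."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 <= e2 + window and s2 <= e1 + window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


@given(
    intervals=st.lists(
        st.tuples(st.integers(1, 200_000), st.integers(1, 20_000)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=50,
    ),
    window=st.integers(0, 10_000),
)
def test_single_linkage_matches_union_find(intervals, window):
    got = sorted(cluster_intervals(intervals, window))
    assert got == brute_force_single_linkage(intervals, window)


def _del_cluster(spans, start=1_000_000, rl=150):
    """Pairs straddling one deletion: all share outer geometry, varying span."""
    return [
        MatePair(f"d{i}", "chr1", "chr1", start - i * 37, start - i * 37 + sp - 1,
                 start - i * 37 + rl - 1, start - i * 37 + sp - rl, sp,
                 LocusClass.INTRA)
        for i, sp in enumerate(spans)
    ]


def test_worked_deletion_size_estimate():
    """5 co-located pairs, mean span 854,712, median library span 6,000
    -> one DEL call of exactly 848,712 bp."""
    spans = [853_712, 854_212, 854_712, 855_212, 855_712]
    assert sum(spans) / 5 == 854_712
    classified = [(mp, MPClass.DELETION_SUPPORT) for mp in _del_cluster(spans)]
    calls = cluster_calls(classified, STATS, CallerConfig(min_support=3))
    assert len(calls) == 1
    call = calls[0]
    assert call.sv_type is SVType.DEL
    assert call.size_estimate == 848_712
    assert call.support == 5


def test_support_below_minimum_gives_no_call():
    classified = [(mp, MPClass.DELETION_SUPPORT) for mp in _del_cluster([854_712, 854_712])]
    assert cluster_calls(classified, STATS, CallerConfig(min_support=3)) == []


def test_distant_groups_make_two_calls():
    g1 = _del_cluster([20_000, 20_100, 20_200], start=100_000)
    g2 = _del_cluster([30_000, 30_100, 30_200], start=1_100_000)
    classified = [(mp, MPClass.DELETION_SUPPORT) for mp in g1 + g2]
    calls = cluster_calls(classified, STATS, CallerConfig(min_support=3))
    assert len(calls) == 2
    assert calls[0].interval.start < calls[1].interval.start


def test_size_floor_drops_small_events():
    spans = [6900, 6950, 7000, 7050]  # mean 6975 -> size 975 < 1000
    classified = [(mp, MPClass.DELETION_SUPPORT) for mp in _del_cluster(spans)]
    assert cluster_calls(classified, STATS, CallerConfig(min_support=3)) == []


def test_span_outlier_excluded_from_cluster():
    """A null-tail pair merged into a deletion cluster must not collapse the
    breakpoint interval: its inconsistent span removes it."""
    good = _del_cluster([50_000, 50_100, 50_200, 50_300], start=1_000_000)
    # an unrelated ~7.3 kb pair ending just left of the cluster footprint
    stray = MatePair("s", "chr1", "chr1", 995_000, 1_002_300, 995_149, 1_002_151,
                     7_301, LocusClass.INTRA)
    classified = [(mp, MPClass.DELETION_SUPPORT) for mp in good + [stray]]
    calls = cluster_calls(classified, STATS, CallerConfig(min_support=4))
    assert len(calls) == 1
    call = calls[0]
    assert call.support == 4  # stray removed
    assert call.size_estimate == pytest.approx(50_150 - 6_000, abs=1)
    assert call.interval.length > 40_000  # interval not collapsed


def reference_caller(classified, stats, cfg):
    """Independent reimplementation of the full clustering+aggregation for
    the oracle-equivalence check: brute-force closure, then the documented
    refinement and size/interval rules."""
    from statistics import median

    out = []
    for cls, svt in ((MPClass.DELETION_SUPPORT, SVType.DEL),
                     (MPClass.INSERTION_SUPPORT, SVType.INS)):
        by_chrom = {}
        for mp, c in classified:
            if c is cls:
                by_chrom.setdefault(mp.chrom1, []).append(mp)
        window = cfg.cluster_window if cfg.cluster_window else int(round(stats.median))
        for chrom, members in by_chrom.items():
            ivs = [(m.outer_start, m.outer_end) for m in members]
            for group in brute_force_single_linkage(ivs, window):
                mems = [members[i] for i in group]
                med = median(m.span for m in mems)
                tol = cfg.span_spread_iqr_mult * stats.iqr
                if tol > 0:
                    mems = [m for m in mems if abs(m.span - med) <= tol]
                if len(mems) < cfg.min_support:
                    continue
                mean_span = sum(m.span for m in mems) / len(mems)
                size = mean_span - stats.median if svt is SVType.DEL else stats.median - mean_span
                size = int(np.floor(size + 0.5))
                if size < cfg.min_size:
                    continue
                s = max(m.left_read_end for m in mems) + 1
                e = min(m.right_read_start for m in mems) - 1
                if e < s:
                    s = e = max(1, (s + e) // 2)
                out.append((chrom, s, e, svt.value, size, len(mems)))
    return sorted(out)


def _random_fixture(rng):
    n = rng.integers(1, 51)
    mps = []
    for i in range(n):
        start = int(rng.integers(1000, 500_000))
        span = int(rng.choice([7300, 7400, 16_000, 16_200, 56_000, 3000, 3100]))
        mps.append(
            MatePair(f"r{i}", "chr1", "chr1", start, start + span - 1,
                     start + 149, start + span - 150, span, LocusClass.INTRA)
        )
    return [(mp, classify_pair(mp, STATS)) for mp in mps]


@pytest.mark.parametrize("n_fixtures", [25])
def test_cluster_calls_matches_reference_implementation(n_fixtures):
    rng = np.random.default_rng(123)
    cfg = CallerConfig(min_support=3)
    for _ in range(n_fixtures):
        classified = _random_fixture(rng)
        calls = cluster_calls(classified, STATS, cfg)
        got = sorted(
            (c.interval.chrom, c.interval.start, c.interval.end,
             c.sv_type.value, c.size_estimate, c.support)
            for c in calls
        )
        assert got == reference_caller(classified, STATS, cfg)


def test_min_support_monotonicity():
    rng = np.random.default_rng(5)
    classified = _random_fixture(rng)
    counts = [
        len(cluster_calls(classified, STATS, CallerConfig(min_support=s)))
        for s in range(1, 8)
    ]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# Library summary
# ---------------------------------------------------------------------------


def test_library_bookkeeping_reported_counts():
    """The reported category counts must sum to the reported intra total,
    and intra/(intra+inter) rounds to 99%."""
    summary = LibrarySummary(
        n_normal=580_754, n_below_lower=418, n_above_upper=426, n_inter=4_473
    )
    assert summary.n_intra == 581_598
    assert summary.n_total == 586_071
    assert summary.intra_share_pct == 99


def test_summarize_library_partitions_input():
    mps = [_mp(s) for s in (6000, 7300, 4700, 7200, 4800)] + [_mp(None)]
    summary = summarize_library(mps, STATS)
    assert (summary.n_normal, summary.n_below_lower, summary.n_above_upper) == (3, 1, 1)
    assert summary.n_inter == 1
    assert summary.n_intra == 5 and summary.n_total == 6


def test_empty_summary_is_all_zero():
    summary = summarize_library([], STATS)
    assert summary.n_total == 0 and summary.intra_share_pct == 0
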