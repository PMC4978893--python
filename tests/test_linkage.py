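"""Positive-site classification, window scan, peak/gap detection, BFR,
and the segregation test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bulkseg import linkage
from bulkseg.types import PooledSiteCall, WindowCount


def site(n_ref, n_alt, m_ref, m_alt, pos=100, chrom="chr1"):
    return PooledSiteCall(chrom, pos, "A", "G", n_ref, n_alt, m_ref, m_alt)


# ---------------------------------------------------------------------------
# biallelic filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,kept",
    [
        ((10, 5, 20, 0), True),   # alt frac 5/15 > 0.2 in the normal bulk
        ((2, 2, 20, 0), False),   # normal depth 4 < 5
        ((19, 1, 20, 0), False),  # alt frac 0.05 <= 0.2
        ((0, 12, 20, 0), True),   # alt-fixed normal bulk allowed
    ],
)
def test_biallelic_filter_default_scope(counts, kept):
    out = linkage.filter_biallelic_sites([site(*counts)])
    assert bool(out) is kept


def test_biallelic_filter_preserves_order_and_handles_empty():
    sites = [site(10, 5, 20, 0, pos=p) for p in (300, 100, 200)]
    assert [s.pos for s in linkage.filter_biallelic_sites(sites)] == [300, 100, 200]
    assert linkage.filter_biallelic_sites([]) == []


def test_biallelic_filter_scopes_differ():
    s = site(10, 5, 0, 20)  # pooled alt frac 25/35 -> ref frac 0.29
    assert linkage.filter_biallelic_sites([s], scope="pooled")
    assert linkage.filter_biallelic_sites([s], scope="each_bulk")
    s2 = site(10, 5, 18, 2)  # mutant alt frac 0.1, not fixed
    assert not linkage.filter_biallelic_sites([s2], scope="each_bulk")
    assert linkage.filter_biallelic_sites([s2], scope="normal_bulk")


# ---------------------------------------------------------------------------
# positive-site classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,tol,positive",
    [
        ((6, 12, 20, 0), 0.0, True),    # normal frac 2/3, mutant pure
        ((12, 6, 20, 0), 0.0, False),   # normal frac 1/3 < 0.5
        ((6, 12, 18, 2), 0.0, False),   # mutant not pure
        ((6, 12, 18, 2), 0.2, True),    # tolerant mode
        ((6, 6, 20, 0), 0.0, True),     # boundary 0.5 is inclusive
    ],
)
def test_positive_classification(counts, tol, positive):
    out = linkage.classify_positive_sites([site(*counts)], mutant_homozygosity_tol=tol)
    assert bool(out) is positive
    if positive:
        assert out[0].mo17_frac_normal == pytest.approx(counts[1] / (counts[0] + counts[1]))


@given(
    counts=st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30),
                  st.integers(0, 30), st.integers(0, 30)),
        min_size=1, max_size=30,
    ),
    frac_lo=st.floats(0.5, 0.9),
    frac_hi=st.floats(0.5, 0.9),
    tol_lo=st.floats(0.0, 0.3),
    tol_hi=st.floats(0.0, 0.3),
)
def test_classification_threshold_monotonicity(counts, frac_lo, frac_hi, tol_lo, tol_hi):
    """Raising the normal-fraction cutoff or lowering the mutant tolerance
    never adds positive sites (set inclusion)."""
    sites = [
        site(a, b, c, d, pos=i + 1)
        for i, (a, b, c, d) in enumerate(counts)
        if a + b > 0 and c + d > 0
    ]
    lo, hi = min(frac_lo, frac_hi), max(frac_lo, frac_hi)
    tlo, thi = min(tol_lo, tol_hi), max(tol_lo, tol_hi)
    strict = {p.site.pos for p in linkage.classify_positive_sites(sites, hi, tlo)}
    loose = {p.site.pos for p in linkage.classify_positive_sites(sites, lo, thi)}
    assert strict <= loose


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def brute_force_counts(positions, chrom_lengths, window, step):
    out = []
    for chrom, length in chrom_lengths.items():
        pos = positions.get(chrom, [])
        start = 1
        while start <= length:
            end = min(start + window - 1, length)
            out.append((chrom, start, end, sum(1 for p in pos if start <= p <= end)))
            start += step
    return out


def test_no_sites_gives_all_zero_windows():
    wins = linkage.sliding_window_counts({}, {"chr1": 100_000})
    assert all(w.count == 0 for w in wins)


def test_single_site_counted_in_window_per_step_windows():
    wins = linkage.sliding_window_counts(
        {"chr1": np.array([555_000])}, {"chr1": 1_000_000}
    )
    hot = [w for w in wins if w.count == 1]
    assert len(hot) == 10
    assert hot[0].start == 460_001 and hot[-1].start == 550_001
    assert all(w.count == 0 for w in wins if w not in hot)


def test_window_counts_match_brute_force(rng):
    chrom_lengths = {"chr1": 7_777, "chr2": 12_345}
    positions = {
        c: np.sort(rng.integers(1, l + 1, size=50))
        for c, l in chrom_lengths.items()
    }
    wins = linkage.sliding_window_counts(positions, chrom_lengths,
                                         window_size=1000, step=250)
    got = [(w.chrom, w.start, w.end, w.count) for w in wins]
    assert got == brute_force_counts(
        {c: p.tolist() for c, p in positions.items()}, chrom_lengths, 1000, 250
    )


def test_window_count_conservation(rng):
    """Sum of window counts equals, per site, the number of windows holding it."""
    length = 50_000
    positions = np.sort(rng.integers(1, length + 1, size=200))
    window, step = 2000, 500
    wins = linkage.sliding_window_counts({"c": positions}, {"c": length}, window, step)
    per_site = sum(
        sum(1 for w in wins if w.start <= p <= w.end) for p in positions.tolist()
    )
    assert sum(w.count for w in wins) == per_site


def test_unknown_chromosome_is_error():
    with pytest.raises(ValueError, match="chrZ"):
        linkage.sliding_window_counts({"chrZ": np.array([5])}, {"chr1": 100})


# ---------------------------------------------------------------------------
# peak and gaps
# ---------------------------------------------------------------------------

def make_windows(counts, chrom="chr1", window=100, step=100, start0=1):
    return [
        WindowCount(chrom, start0 + i * step, start0 + i * step + window - 1, c)
        for i, c in enumerate(counts)
    ]


def test_peak_and_region_from_counts():
    wins = make_windows([0, 0, 5, 9, 7, 0])
    peak = linkage.detect_linkage_peak(wins, region_frac=0.25)
    assert peak.peak_window.count == 9
    assert peak.peak_window.start == wins[3].start
    assert (peak.region_start, peak.region_end) == (wins[2].start, wins[4].end)


def test_peak_tie_falls_back_to_genome_order():
    wins = make_windows([3, 0], chrom="chr1") + make_windows([3, 0], chrom="chr2")
    peak = linkage.detect_linkage_peak(wins)
    assert peak.chrom == "chr1" and peak.n_ties == 2


def test_peak_tie_prefers_local_support():
    # the later tied window has the stronger neighbourhood and must win
    wins = make_windows([4, 0, 0, 0, 0, 0, 0, 0, 3, 4], window=100, step=100)
    peak = linkage.detect_linkage_peak(wins, tie_support_radius=150)
    assert peak.peak_window.start == wins[9].start


def test_all_zero_counts_is_no_signal():
    assert linkage.detect_linkage_peak(make_windows([0, 0, 0])) is None


def test_gap_spans_zero_run():
    wins = make_windows([4, 6, 0, 0, 0, 0, 0, 7, 5])
    peak = linkage.detect_linkage_peak(wins)
    (gap,) = linkage.detect_linkage_gaps(wins, peak, flank=10_000, min_gap_windows=5)
    assert gap.n_zero_windows == 5
    assert (gap.start, gap.end) == (wins[1].end + 1, wins[7].start - 1)


def test_gap_at_chromosome_edge_not_reported():
    wins = make_windows([0, 0, 0, 0, 0, 6, 4, 2, 2])
    peak = linkage.detect_linkage_peak(wins)
    assert linkage.detect_linkage_gaps(wins, peak, flank=10_000, min_gap_windows=5) == []


def test_short_zero_run_with_overlapping_windows_is_suppressed():
    # 5 zero windows at 10x-overlapping geometry leave no positive span
    wins = make_windows([4, 6, 0, 0, 0, 0, 0, 7, 5], window=1000, step=100)
    peak = linkage.detect_linkage_peak(wins)
    assert linkage.detect_linkage_gaps(wins, peak, flank=10_000, min_gap_windows=5) == []


# ---------------------------------------------------------------------------
# BFR and segregation
# ---------------------------------------------------------------------------

def test_bfr_values():
    assert linkage.compute_bfr(site(5, 5, 10, 10)) == pytest.approx(1.0)
    assert linkage.compute_bfr(site(2, 8, 8, 2)) == pytest.approx(4.0)
    assert linkage.compute_bfr(site(6, 12, 20, 0)) == math.inf
    expect = (12 / 18 + 0.01) / (0 / 20 + 0.01)
    assert linkage.compute_bfr(site(6, 12, 20, 0), pseudo=0.01) == pytest.approx(expect)
    with pytest.raises(ValueError):
        linkage.compute_bfr(PooledSiteCall("c", 1, "A", "G", 0, 0, 5, 5))


def test_segregation_chisq():
    chi2, p, df = linkage.segregation_chisq(75, 25)
    assert chi2 == pytest.approx(0.0) and df == 1
    chi2, _, _ = linkage.segregation_chisq(90, 10)
    assert chi2 == pytest.approx(12.0)
    chi2, p, _ = linkage.segregation_chisq(300, 100)
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        linkage.segregation_chisq(-1, 5)
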