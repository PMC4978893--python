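"""Positive-site classification and the sliding-window linkage scan.

The mapping signal unit is the *positive site*: a biallelic marker between
the two parental genomes whose Mo17-origin (non-reference) allele has read
fraction >= 0.5 in the normal bulk while the mutant bulk carries the pure
B73 allele.  Counting positive sites in 100-kb windows moved in 10-kb steps
along each chromosome produces a linkage peak at the causative locus, and a
run of zero-count windows inside the peak is the footprint of a deletion
that removed every expressed marker locally.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .types import LinkageGap, LinkagePeak, PooledSiteCall, PositiveSite, WindowCount

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 10_000


def filter_biallelic_sites(
    sites: Sequence[PooledSiteCall],
    min_depth: int = 5,
    min_allele_frac: float = 0.2,
    scope: str = "normal_bulk",
) -> list[PooledSiteCall]:
    """Keep sites callable in both bulks.

    A site is kept when both bulks have depth >= ``min_depth`` and the
    allele-fraction rule holds under the configured ``scope``:

    * ``normal_bulk`` (default): both alleles exceed ``min_allele_frac`` of
      the normal-bulk depth, or the normal bulk is alt-fixed.  The mutant
      bulk is exempt because downstream classification requires it to be
      ref-pure, which a both-alleles rule would contradict.
    * ``pooled``: the rule is evaluated on summed counts of both bulks, or
      either bulk is fixed for one allele.
    * ``each_bulk``: the rule must hold (or the bulk be fixed) in each bulk.

    Input order is preserved.
    """
    if not 0 < min_allele_frac <= 0.5:
        raise ValueError("min_allele_frac must be in (0, 0.5]")
    if scope not in ("normal_bulk", "pooled", "each_bulk"):
        raise ValueError(f"unknown allele-fraction scope {scope!r}")

    def frac_ok(ref: int, alt: int) -> bool:
        tot = ref + alt
        if tot == 0:
            return False
        return min(ref, alt) / tot > min_allele_frac

    kept = []
    for s in sites:
        if s.n_depth < min_depth or s.m_depth < min_depth:
            continue
        if scope == "normal_bulk":
            ok = frac_ok(s.n_ref, s.n_alt) or s.n_ref == 0
        elif scope == "pooled":
            fixed = 0 in (s.n_ref, s.n_alt, s.m_ref, s.m_alt)
            ok = frac_ok(s.n_ref + s.m_ref, s.n_alt + s.m_alt) or fixed
        else:  # each_bulk
            ok = (frac_ok(s.n_ref, s.n_alt) or s.n_ref == 0 or s.n_alt == 0) and (
                frac_ok(s.m_ref, s.m_alt) or s.m_ref == 0 or s.m_alt == 0
            )
        if ok:
            kept.append(s)
    return kept


def classify_positive_sites(
    sites: Sequence[PooledSiteCall],
    min_normal_mo17_frac: float = 0.5,
    mutant_homozygosity_tol: float = 0.0,
) -> list[PositiveSite]:
    """Classify sites whose allele pattern indicates linkage.

    Positive iff the alt (Mo17-origin) read fraction in the normal bulk is
    >= ``min_normal_mo17_frac`` (inclusive — a hemizygous-heavy pool sits at
    exactly 0.5) and the mutant-bulk alt fraction is <= the homozygosity
    tolerance (0 by default: not a single non-B73 read).  Zero-depth sites
    are skipped with a log entry.
    """
    out = []
    for s in sites:
        if s.n_depth == 0 or s.m_depth == 0:
            log.info("skipping zero-depth site %s:%d", s.chrom, s.pos)
            continue
        nf = s.n_alt / s.n_depth
        mf = s.m_alt / s.m_depth
        if nf >= min_normal_mo17_frac and mf <= mutant_homozygosity_tol:
            out.append(PositiveSite(site=s, mo17_frac_normal=nf, mutant_alt_frac=mf))
    return out


def positive_positions(positives: Iterable[PositiveSite]) -> dict[str, np.ndarray]:
    """Group positive-site coordinates per chromosome, sorted."""
    by_chrom: dict[str, list[int]] = {}
    for p in positives:
        by_chrom.setdefault(p.site.chrom, []).append(p.site.pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def sliding_window_counts(
    positions: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowCount]:
    """Count positive sites in sliding windows on a fixed grid.

    Windows are anchored at starts 1, 1+step, 1+2*step, ... up to the last
    start <= chromosome length; each window spans
    ``[start, min(start + window_size - 1, chrom_length)]``.  A site interior
    to a chromosome is therefore counted in exactly ``window_size/step``
    windows.
    """
    if window_size % step != 0:
        log.warning("window_size %d is not a multiple of step %d", window_size, step)
    unknown = set(positions) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"positions on unknown chromosome(s): {sorted(unknown)}")
    windows: list[WindowCount] = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(positions.get(chrom, np.empty(0, dtype=np.int64)))
        if pos.size and (pos.min() < 1 or pos.max() > length):
            raise ValueError(f"position outside [1, {length}] on {chrom}")
        starts = np.arange(1, length + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window_size - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        counts = hi - lo
        windows.extend(
            WindowCount(chrom=chrom, start=int(s), end=int(e), count=int(c))
            for s, e, c in zip(starts, ends, counts)
        )
    return windows


def detect_linkage_peak(
    windows: Sequence[WindowCount],
    region_frac: float = 0.25,
    tie_support_radius: int = 500_000,
) -> LinkagePeak | None:
    """Locate the genome-wide maximal window and its surrounding peak region.

    With sparse markers many windows tie at the maximal count, so ties
    resolve by local support: the tied window whose same-chromosome
    neighbourhood within ``tie_support_radius`` has the largest summed
    count wins (the radius must stay below the linkage-decay scale of
    1-2 cM or distant windows borrow the peak's own support).  Residual
    ties fall back to genome order — first chromosome as given, then
    lowest start — and are logged.  The peak region is the maximal run of
    contiguous windows on the peak chromosome with count >= ``region_frac``
    * max that contains the peak window.  Returns None ("no linkage
    signal") when every count is zero.
    """
    if not windows:
        return None
    max_count = max(w.count for w in windows)
    if max_count == 0:
        log.info("no linkage signal: all window counts are zero")
        return None
    ties = [w for w in windows if w.count == max_count]
    if len(ties) > 1:
        by_chrom: dict[str, list[WindowCount]] = {}
        for w in windows:
            by_chrom.setdefault(w.chrom, []).append(w)

        def support(w: WindowCount) -> int:
            return sum(
                x.count for x in by_chrom[w.chrom]
                if abs(x.start - w.start) <= tie_support_radius
            )

        best = max(support(w) for w in ties)
        ties = [w for w in ties if support(w) == best]
    peak_win = ties[0]
    if len(ties) > 1:
        log.info("%d windows tied at max count %d; keeping %s:%d",
                 len(ties), max_count, peak_win.chrom, peak_win.start)
    chrom_wins = sorted((w for w in windows if w.chrom == peak_win.chrom),
                        key=lambda w: w.start)
    threshold = region_frac * max_count
    idx = next(i for i, w in enumerate(chrom_wins) if w.start == peak_win.start)
    lo = idx
    while lo > 0 and chrom_wins[lo - 1].count >= threshold:
        lo -= 1
    hi = idx
    while hi + 1 < len(chrom_wins) and chrom_wins[hi + 1].count >= threshold:
        hi += 1
    return LinkagePeak(
        chrom=peak_win.chrom,
        peak_window=peak_win,
        region_start=chrom_wins[lo].start,
        region_end=chrom_wins[hi].end,
        n_ties=len(ties),
    )


def detect_linkage_gaps(
    windows: Sequence[WindowCount],
    peak: LinkagePeak,
    flank: int = 3_000_000,
    min_gap_windows: int = 5,
) -> list[LinkageGap]:
    """Report zero-count runs near the linkage peak as candidate deletion
    footprints.

    Within ``[region_start - flank, region_end + flank]`` on the peak
    chromosome, every maximal run of >= ``min_gap_windows`` consecutive
    zero-count windows flanked on both sides by nonzero windows becomes a
    gap spanning (end of last preceding nonzero window + 1) to (start of
    next nonzero window - 1).  With overlapping windows a short zero-run
    yields an empty span (the flanking windows still overlap); such runs are
    suppressed.  Runs touching a chromosome edge lack a flank and are not
    reported.
    """
    span_lo = peak.region_start - flank
    span_hi = peak.region_end + flank
    wins = sorted(
        (w for w in windows
         if w.chrom == peak.chrom and w.start >= span_lo and w.end <= span_hi),
        key=lambda w: w.start,
    )
    gaps: list[LinkageGap] = []
    i = 0
    n = len(wins)
    while i < n:
        if wins[i].count == 0:
            j = i
            while j + 1 < n and wins[j + 1].count == 0:
                j += 1
            run = j - i + 1
            has_left = i > 0 and wins[i - 1].count > 0
            has_right = j + 1 < n and wins[j + 1].count > 0
            if run >= min_gap_windows and has_left and has_right:
                start = wins[i - 1].end + 1
                end = wins[j + 1].start - 1
                if start <= end:
                    gaps.append(LinkageGap(chrom=peak.chrom, start=start, end=end,
                                           n_zero_windows=run))
            i = j + 1
        else:
            i += 1
    return gaps


def compute_bfr(site: PooledSiteCall, pseudo: float = 0.0) -> float:
    """Bulk frequency ratio: the normal-bulk alt fraction over the
    mutant-bulk alt fraction, each offset by ``pseudo``.

    The comparison statistic of simpler bulked-segregant analyses; with
    ``pseudo=0`` and a ref-pure mutant bulk the ratio is +inf (documented
    sentinel).  Noisier than the positive-site count: unlinked sites sit
    near 1 and thresholding BFR >= 1 floods the scan with false positives.
    """
    if site.n_depth == 0 or site.m_depth == 0:
        raise ValueError(f"zero depth at {site.chrom}:{site.pos}")
    nf = site.n_alt / site.n_depth
    mf = site.m_alt / site.m_depth
    denom = mf + pseudo
    if denom == 0:
        return math.inf
    return (nf + pseudo) / denom


def segregation_chisq(
    n_normal: int,
    n_mutant: int,
    expected_ratio: tuple[float, float] = (3.0, 1.0),
) -> tuple[float, float, int]:
    """Chi-square goodness-of-fit of kernel counts to Mendelian 3:1.

    Returns ``(chi2, p, df=1)``; a recessive single-locus mutant segregates
    3 normal : 1 mutant on a selfed F1 ear.
    """
    if n_normal < 0 or n_mutant < 0:
        raise ValueError("counts must be non-negative")
    total = n_normal + n_mutant
    if total == 0:
        raise ValueError("no observations")
    w = expected_ratio[0] + expected_ratio[1]
    f_exp = [total * expected_ratio[0] / w, total * expected_ratio[1] / w]
    chi2, p = stats.chisquare([n_normal, n_mutant], f_exp=f_exp)
    return float(chi2), float(p), 1
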