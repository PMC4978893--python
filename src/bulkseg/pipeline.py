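"""End-to-end orchestration: variant calls + depth tracks + gene counts in,
ranked candidate report out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import exome, integrate, linkage
from .types import (
    CandidateReport,
    DeletionCall,
    DepthTrack,
    ExonRecord,
    GeneCountTable,
    GeneExpression,
    LinkageGap,
    LinkagePeak,
    PooledSiteCall,
    WindowCount,
)


@dataclass
class ScanResult:
    windows: list[WindowCount]
    peak: LinkagePeak | None
    gaps: list[LinkageGap]
    n_biallelic: int
    n_positive: int


def run_linkage_scan(
    calls: Sequence[PooledSiteCall],
    chrom_lengths: Mapping[str, int],
    *,
    window_size: int = linkage.DEFAULT_WINDOW,
    step: int = linkage.DEFAULT_STEP,
    min_depth: int = 5,
    min_allele_frac: float = 0.2,
    min_normal_mo17_frac: float = 0.5,
    mutant_homozygosity_tol: float = 0.0,
    region_frac: float = 0.25,
    gap_flank: int = 3_000_000,
    min_gap_windows: int = 5,
) -> ScanResult:
    """Filter, classify, window-scan, and locate the peak and its gaps."""
    biallelic = linkage.filter_biallelic_sites(calls, min_depth, min_allele_frac)
    positives = linkage.classify_positive_sites(
        biallelic, min_normal_mo17_frac, mutant_homozygosity_tol
    )
    windows = linkage.sliding_window_counts(
        linkage.positive_positions(positives), chrom_lengths, window_size, step
    )
    peak = linkage.detect_linkage_peak(windows, region_frac)
    gaps = (
        linkage.detect_linkage_gaps(windows, peak, gap_flank, min_gap_windows)
        if peak is not None else []
    )
    return ScanResult(windows=windows, peak=peak, gaps=gaps,
                      n_biallelic=len(biallelic), n_positive=len(positives))


def run_deletion_calling(
    control_track: DepthTrack,
    mutant_track: DepthTrack,
    exons: Sequence[ExonRecord],
    *,
    min_control_norm: float = exome.DEFAULT_MIN_CONTROL_NORM,
    max_mutant_D: float = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[str], list[DeletionCall]]:
    """Accumulate depth, call deleted exons, merge into deletion calls."""
    control = exome.accumulate_exon_depth(control_track, exons)
    mutant = exome.accumulate_exon_depth(mutant_track, exons)
    deleted = exome.call_deleted_exons(
        control, mutant, min_control_norm, max_mutant_D,
        control_total_depth=control_track.total(),
        mutant_total_depth=mutant_track.total(),
    )
    calls = exome.build_deletion_calls(
        deleted, exons, mutant_track,
        chrom_lengths=dict(chrom_lengths) if chrom_lengths else None,
    )
    return deleted, calls


def run_candidate_integration(
    mutant_id: str,
    scan: ScanResult,
    deletions: Sequence[DeletionCall],
    gene_counts: GeneCountTable | None = None,
    gene_spans: Mapping[str, tuple[str, int, int]] | None = None,
    *,
    min_dropout_n_norm: float = 10.0,
    known_chroms: Sequence[str] | None = None,
) -> CandidateReport:
    """Rank deletions and (peak-region) expression dropouts into a report."""
    dropouts: list[GeneExpression] = []
    if gene_counts is not None and scan.peak is not None:
        expr = integrate.normalize_counts(gene_counts)
        if gene_spans:
            for g in expr:
                span = gene_spans.get(g.gene_id)
                if span is not None:
                    g.chrom, g.start, g.end = span
        dropouts = integrate.find_expression_dropout_genes(
            expr,
            (scan.peak.chrom, scan.peak.region_start, scan.peak.region_end),
            min_n_norm=min_dropout_n_norm,
        )
    return integrate.rank_candidates(
        mutant_id, scan.peak, scan.gaps, deletions, dropouts,
        known_chroms=known_chroms,
    )
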