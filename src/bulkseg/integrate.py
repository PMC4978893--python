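"""Candidate integration: combine the linkage peak/gaps, depth-based
deletion calls, and bulk expression into one ranked causative-candidate
report.

Evidence classes, strongest first:

1. ``deletion_in_gap`` — a called deletion inside a linkage gap;
2. ``deletion_in_peak`` — a called deletion inside the peak region;
3. ``expression_dropout`` — a gene expressed in the normal bulk with zero
   mutant-bulk reads, inside the peak region (the detection mode available
   when no exome data exist);
4. ``deletion_outside_peak`` — any other called deletion.

Within a class, candidates order by distance from the peak-window midpoint
to their nearest edge.  When classes 1–3 are all empty the report carries
an explicit note that the causative lesion may be regulatory or intronic.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

from .types import (
    Candidate,
    CandidateReport,
    DeletionCall,
    GeneCountTable,
    GeneExpression,
    LinkageGap,
    LinkagePeak,
)

log = logging.getLogger(__name__)

FC_PSEUDOCOUNT = 0.05
NO_EXONIC_NOTE = (
    "no exonic deletion or expression dropout under the linkage peak - "
    "consider a regulatory or intronic mutation"
)

_EVIDENCE_RANK = {
    "deletion_in_gap": 0,
    "deletion_in_peak": 1,
    "expression_dropout": 2,
    "deletion_outside_peak": 3,
}


def normalize_counts(raw: GeneCountTable) -> list[GeneExpression]:
    """Counts-per-million normalization of both bulks (``fc`` left unset)."""
    if raw.n_library_size <= 0 or raw.m_library_size <= 0:
        raise ValueError("library sizes must be > 0")
    return [
        GeneExpression(
            gene_id=gene,
            n_norm=1e6 * n / raw.n_library_size,
            m_norm=1e6 * m / raw.m_library_size,
        )
        for gene, (n, m) in raw.counts.items()
    ]


def expression_fold_change(n_norm: float, m_norm: float) -> float:
    """Pseudocounted fold change ``n / (m + 0.05)``; the offset keeps the
    ratio finite for dropout genes with zero mutant reads."""
    if n_norm < 0 or m_norm < 0:
        raise ValueError("normalized counts must be >= 0")
    return n_norm / (m_norm + FC_PSEUDOCOUNT)


def find_expression_dropout_genes(
    expr: Sequence[GeneExpression],
    region: tuple[str, int, int],
    min_n_norm: float,
    max_m_norm: float = 0.0,
) -> list[GeneExpression]:
    """Genes overlapping ``region`` with high normal-bulk and at most
    ``max_m_norm`` mutant-bulk expression, sorted by fold change descending.

    Widening the region can only add genes (monotone), which is how a
    dropout hit is extended to its neighbours for PCR follow-up.
    """
    chrom, rstart, rend = region
    hits = []
    for g in expr:
        if g.chrom is None or g.start is None or g.end is None:
            continue
        if g.chrom != chrom or g.end < rstart or g.start > rend:
            continue
        if g.n_norm >= min_n_norm and g.m_norm <= max_m_norm:
            g.fc = expression_fold_change(g.n_norm, g.m_norm)
            hits.append(g)
    return sorted(hits, key=lambda g: (-(g.fc or 0.0), g.gene_id))


def _distance(peak: LinkagePeak, chrom: str, start: int, end: int) -> float:
    """Distance from the peak-window midpoint to the interval's nearest
    edge; infinite across chromosomes, 0 when the midpoint falls inside."""
    if chrom != peak.chrom:
        return math.inf
    mid = (peak.peak_window.start + peak.peak_window.end) / 2
    if start <= mid <= end:
        return 0.0
    return min(abs(start - mid), abs(end - mid))


def _overlaps(start: int, end: int, lo: int, hi: int) -> bool:
    return start <= hi and end >= lo


def rank_candidates(
    mutant_id: str,
    peak: LinkagePeak | None,
    gaps: Sequence[LinkageGap],
    deletions: Sequence[DeletionCall],
    dropouts: Sequence[GeneExpression] = (),
    known_chroms: Sequence[str] | None = None,
) -> CandidateReport:
    """Build the ranked causative-candidate report for one mutant.

    The ordering is a deterministic total order (evidence class, then
    distance to the peak-window midpoint, then label), so the report is
    invariant to input order.
    """
    if known_chroms is not None:
        known = set(known_chroms)
        bad = [d for d in deletions if d.chrom not in known]
        if peak is not None and peak.chrom not in known:
            raise ValueError(f"peak chromosome {peak.chrom!r} not in genome")
        if bad:
            raise ValueError(
                f"deletion chromosome(s) not in genome: {sorted({d.chrom for d in bad})}"
            )
    candidates: list[Candidate] = []
    for d in deletions:
        if peak is not None and d.chrom == peak.chrom and any(
            _overlaps(d.left_bp + 1, d.right_bp - 1, g.start, g.end) for g in gaps
        ):
            evidence = "deletion_in_gap"
        elif peak is not None and d.chrom == peak.chrom and _overlaps(
            d.left_bp + 1, d.right_bp - 1, peak.region_start, peak.region_end
        ):
            evidence = "deletion_in_peak"
        else:
            evidence = "deletion_outside_peak"
        dist = (
            _distance(peak, d.chrom, d.left_bp + 1, d.right_bp - 1)
            if peak is not None else math.inf
        )
        candidates.append(
            Candidate(
                label="|".join(d.genes) or f"{d.chrom}:{d.left_bp}-{d.right_bp}",
                chrom=d.chrom, start=d.left_bp + 1, end=d.right_bp - 1,
                evidence=evidence, distance_to_peak=dist,
                fc=None, deletion=d,
            )
        )
    for g in dropouts:
        if g.chrom is None:
            continue
        dist = _distance(peak, g.chrom, g.start, g.end) if peak is not None else math.inf
        candidates.append(
            Candidate(
                label=g.gene_id, chrom=g.chrom, start=g.start, end=g.end,
                evidence="expression_dropout", distance_to_peak=dist, fc=g.fc,
            )
        )
    candidates.sort(key=lambda c: (_EVIDENCE_RANK[c.evidence], c.distance_to_peak, c.label))
    top_classes = {c.evidence for c in candidates} & {
        "deletion_in_gap", "deletion_in_peak", "expression_dropout",
    }
    note = "" if top_classes else NO_EXONIC_NOTE
    return CandidateReport(
        mutant_id=mutant_id,
        peak=peak,
        gaps=list(gaps),
        candidates=candidates,
        note=note,
    )


def report_to_rows(report: CandidateReport) -> list[dict]:
    """Flatten a report for TSV output."""
    rows = []
    for rank, c in enumerate(report.candidates, start=1):
        rows.append(
            {
                "mutant_id": report.mutant_id,
                "rank": rank,
                "candidate": c.label,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "evidence": c.evidence,
                "distance_to_peak": c.distance_to_peak,
                "fc": "" if c.fc is None else round(c.fc, 3),
            }
        )
    return rows
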