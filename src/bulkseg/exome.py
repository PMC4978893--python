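"""Deleted-exon calling from exome-capture read depth.

For each annotated exon the accumulated depth ``D`` is the sum of per-base
depths over the exon body, normalized as ``1e9 * D / (L * D_a)`` where ``L``
is the exon length and ``D_a`` the total accumulated depth of the sample.
An exon is called deleted when the control (wild-type) normalized depth is
strictly greater than 30 while the mutant accumulated depth is exactly 0.
Runs of consecutively deleted exons merge into a single deletion call whose
breakpoints are the nearest covered positions flanking the zero-coverage
run, and the deleted length is ``right_bp - left_bp - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .types import DeletionCall, DepthTrack, ExonDepth, ExonRecord

log = logging.getLogger(__name__)

DEFAULT_MIN_CONTROL_NORM = 30.0


def accumulate_exon_depth(track: DepthTrack, exons: Sequence[ExonRecord]) -> list[ExonDepth]:
    """Sum per-base depth over each exon body (``norm`` left unset).

    Exons on chromosomes absent from the track get D = 0 with a log entry;
    positions beyond the covered universe read as depth 0.
    """
    missing_chroms = {e.chrom for e in exons} - set(track.chroms)
    for chrom in sorted(missing_chroms):
        log.info("chromosome %s absent from depth track; exons get D=0", chrom)
    return [
        ExonDepth(exon=e, D=track.range_sum(e.chrom, e.start, e.end))
        for e in exons
    ]


def normalize_exon_depth(D: float, L: int, D_a: float) -> float:
    """Normalized accumulated depth ``1e9 * D / (L * D_a)``.

    Invariant under uniform rescaling of all depths (D -> cD, D_a -> cD_a).
    """
    if L < 1:
        raise ValueError("exon length must be >= 1")
    if D_a <= 0:
        raise ValueError("total accumulated depth D_a must be > 0 (empty sample?)")
    return 1e9 * D / (L * D_a)


def call_deleted_exons(
    control: Sequence[ExonDepth],
    mutant: Sequence[ExonDepth],
    min_control_norm: float = DEFAULT_MIN_CONTROL_NORM,
    max_mutant_D: float = 0,
    control_total_depth: float | None = None,
    mutant_total_depth: float | None = None,
) -> list[str]:
    """Call exons deleted in the mutant: control norm strictly > 30 and raw
    mutant D <= ``max_mutant_D`` (default exactly 0).

    Control and mutant must cover the same exon universe (keyed by exon_id).
    ``D_a`` defaults to the sum of accumulated depths over the supplied
    exons (for capture data essentially the whole-sample depth, since
    uncaptured regions contribute nothing); pass explicit whole-sample
    totals to override.  Fills in ``norm`` on both inputs as a side effect.
    """
    ctl = {ed.exon.exon_id: ed for ed in control}
    mut = {ed.exon.exon_id: ed for ed in mutant}
    only = set(ctl) ^ set(mut)
    if only:
        raise ValueError(f"exon(s) present in one sample only: {sorted(only)[:5]}")
    ctl_da = control_total_depth if control_total_depth is not None else sum(ed.D for ed in control)
    mut_da = mutant_total_depth if mutant_total_depth is not None else sum(ed.D for ed in mutant)
    deleted = []
    for exon_id, ced in ctl.items():
        med = mut[exon_id]
        ced.norm = normalize_exon_depth(ced.D, ced.exon.length, ctl_da)
        med.norm = normalize_exon_depth(med.D, med.exon.length, mut_da) if mut_da > 0 else 0.0
        if ced.norm > min_control_norm and med.D <= max_mutant_D:
            deleted.append(exon_id)
    return deleted


@dataclass(frozen=True)
class DeletionSpan:
    left_bp: int
    right_bp: int
    left_truncated: bool = False
    right_truncated: bool = False


def estimate_deletion_span(
    track_mutant: DepthTrack,
    deleted_exons: Sequence[ExonRecord],
    min_flank_depth: float = 1,
    chrom_length: int | None = None,
) -> DeletionSpan:
    """Extend a run of deleted exons outward to the nearest covered bases.

    ``left_bp`` is the greatest position below the leftmost deleted base
    with depth >= ``min_flank_depth``; ``right_bp`` the least such position
    above the rightmost deleted base.  The open interval between them is
    verified coverage-free.  A side with no covered flank is reported at the
    chromosome bound with a truncation flag.
    """
    if not deleted_exons:
        raise ValueError("no deleted exons supplied")
    chroms = {e.chrom for e in deleted_exons}
    if len(chroms) > 1:
        raise ValueError(f"deleted exons span several chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    left_most = min(e.start for e in deleted_exons)
    right_most = max(e.end for e in deleted_exons)
    left = track_mutant.last_covered_before(chrom, left_most, min_flank_depth)
    right = track_mutant.first_covered_after(chrom, right_most, min_flank_depth)
    left_trunc = left is None
    right_trunc = right is None
    if left is None:
        left = 1
    if right is None:
        right = chrom_length if chrom_length is not None else max(
            (track_mutant.max_covered(chrom) or 0), right_most
        ) + 1
    pos = track_mutant.positions(chrom)
    dep = track_mutant.depths(chrom)
    mask = (pos > left) & (pos < right) & (dep >= min_flank_depth)
    if mask.any():
        inner = pos[mask][:5].tolist()
        raise ValueError(
            f"covered position(s) inside presumed deletion on {chrom}: {inner}"
        )
    return DeletionSpan(left_bp=int(left), right_bp=int(right),
                        left_truncated=left_trunc, right_truncated=right_trunc)


def deletion_length(left_bp: int, right_bp: int) -> int:
    """Deleted bases between two flanking breakpoints: right - left - 1.

    The breakpoints are the last/first retained positions, so adjacent
    coordinates mean nothing was deleted.
    """
    if left_bp >= right_bp:
        raise ValueError("left breakpoint must be < right breakpoint")
    return right_bp - left_bp - 1


def cdna_deletion_effect(deleted_exon_lengths: Sequence[int]) -> dict:
    """Translate deleted exon lengths into the cDNA and protein effect.

    Returns ``{"cdna_bp", "in_frame", "aa_removed"}``: the summed exonic
    length, whether it is a multiple of 3 (splicing the flanking exons
    together preserves the reading frame), and the number of amino acids
    removed when in frame (None otherwise).
    """
    if any(l < 1 for l in deleted_exon_lengths):
        raise ValueError("exon lengths must be >= 1")
    cdna = int(sum(deleted_exon_lengths))
    in_frame = cdna % 3 == 0
    return {
        "cdna_bp": cdna,
        "in_frame": in_frame,
        "aa_removed": cdna // 3 if in_frame else None,
    }


def build_deletion_calls(
    deleted_exon_ids: Sequence[str],
    exons: Sequence[ExonRecord],
    track_mutant: DepthTrack,
    min_flank_depth: float = 1,
    chrom_lengths: dict[str, int] | None = None,
    provenance: str = "exome_depth",
) -> list[DeletionCall]:
    """Merge deleted exons into deletion calls with estimated breakpoints.

    Deleted exons that are consecutive in chromosome order — no intervening
    non-deleted exon — merge into a single call; separated groups become
    separate calls.  A group is further split wherever the mutant track
    shows coverage between two of its exons: retained sequence between
    zero-coverage runs means two distinct deletions.
    """
    deleted = set(deleted_exon_ids)
    unknown = deleted - {e.exon_id for e in exons}
    if unknown:
        raise ValueError(f"deleted exon(s) not in annotation: {sorted(unknown)[:5]}")
    ordered = sorted(exons, key=lambda e: (e.chrom, e.start, e.end))
    groups: list[list[ExonRecord]] = []
    current: list[ExonRecord] = []
    for e in ordered:
        if e.exon_id in deleted:
            if current and current[-1].chrom != e.chrom:
                groups.append(current)
                current = []
            current.append(e)
        else:
            if current:
                groups.append(current)
                current = []
    if current:
        groups.append(current)
    # split a group where retained (covered) sequence separates its exons
    split_groups: list[list[ExonRecord]] = []
    for group in groups:
        part = [group[0]]
        for prev, nxt in zip(group, group[1:]):
            between = track_mutant.first_covered_after(prev.chrom, prev.end, min_flank_depth)
            if between is not None and between < nxt.start:
                split_groups.append(part)
                part = [nxt]
            else:
                part.append(nxt)
        split_groups.append(part)
    groups = split_groups
    calls = []
    for group in groups:
        chrom = group[0].chrom
        span = estimate_deletion_span(
            track_mutant, group, min_flank_depth,
            chrom_length=(chrom_lengths or {}).get(chrom),
        )
        genes: list[str] = []
        for e in group:
            if e.gene_id not in genes:
                genes.append(e.gene_id)
        calls.append(
            DeletionCall(
                chrom=chrom,
                left_bp=span.left_bp,
                right_bp=span.right_bp,
                length=deletion_length(span.left_bp, span.right_bp),
                deleted_exons=tuple(e.exon_id for e in group),
                genes=tuple(genes),
                provenance=provenance,
                left_truncated=span.left_truncated,
                right_truncated=span.right_truncated,
            )
        )
    return calls
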