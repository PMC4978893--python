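"""Canonical in-memory types shared by every pipeline stage.

All coordinates are 1-based inclusive throughout the package; BED and
bedGraph conversions happen at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


@dataclass(frozen=True)
class PooledSiteCall:
    """One biallelic variant site with read counts in the two bulks.

    The reference allele is the B73 allele (reads are mapped to the B73
    reference); the alternate allele is taken to be of Mo17 origin.
    ``n_*`` counts come from the normal (wild-type + hemizygous) bulk and
    ``m_*`` from the mutant bulk.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    n_ref: int
    n_alt: int
    m_ref: int
    m_alt: int
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("n_ref", "n_alt", "m_ref", "m_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_depth(self) -> int:
        return self.n_ref + self.n_alt

    @property
    def m_depth(self) -> int:
        return self.m_ref + self.m_alt


@dataclass(frozen=True)
class ExonRecord:
    """One annotated exon, 1-based inclusive coordinates."""

    gene_id: str
    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"exon {self.exon_id}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class DepthTrack:
    """Sparse per-base sequencing depth, keyed by chromosome.

    Positions absent from the track have depth 0 (the natural state for
    capture-style data where most of the genome is uncovered).  Internally
    each chromosome holds a sorted array of covered positions and a parallel
    depth array.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (pos, dep) in data.items():
                self.add_positions(chrom, pos, dep)

    def add_positions(self, chrom: str, pos: Iterable[int], depth: Iterable[float]) -> None:
        """Add (position, depth) pairs; duplicate positions are summed."""
        pos = np.asarray(pos, dtype=np.int64)
        dep = np.asarray(depth, dtype=np.float64)
        if pos.shape != dep.shape:
            raise ValueError("position and depth arrays differ in length")
        if pos.size and pos.min() < 1:
            raise ValueError("positions must be >= 1")
        if dep.size and dep.min() < 0:
            raise ValueError(f"negative depth on {chrom}")
        if chrom in self._data:
            old_pos, old_dep = self._data[chrom]
            pos = np.concatenate([old_pos, pos])
            dep = np.concatenate([old_dep, dep])
        uniq, inv = np.unique(pos, return_inverse=True)
        summed = np.zeros(uniq.size, dtype=np.float64)
        np.add.at(summed, inv, dep)
        keep = summed > 0
        self._data[chrom] = (uniq[keep], summed[keep])

    def add_interval(self, chrom: str, start: int, end: int, depth: float) -> None:
        """Add constant depth over the 1-based inclusive interval [start, end]."""
        if end < start:
            raise ValueError(f"interval end {end} < start {start}")
        pos = np.arange(start, end + 1, dtype=np.int64)
        self.add_positions(chrom, pos, np.full(pos.size, depth))

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def positions(self, chrom: str) -> np.ndarray:
        if chrom not in self._data:
            return np.empty(0, dtype=np.int64)
        return self._data[chrom][0]

    def depths(self, chrom: str) -> np.ndarray:
        if chrom not in self._data:
            return np.empty(0, dtype=np.float64)
        return self._data[chrom][1]

    def depth(self, chrom: str, pos: int) -> float:
        if chrom not in self._data:
            return 0.0
        p, d = self._data[chrom]
        i = np.searchsorted(p, pos)
        if i < p.size and p[i] == pos:
            return float(d[i])
        return 0.0

    def range_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of depths over the inclusive interval [start, end]."""
        if chrom not in self._data:
            return 0.0
        p, d = self._data[chrom]
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="right")
        return float(d[lo:hi].sum())

    def total(self) -> float:
        """Total accumulated depth over all covered positions (D_a)."""
        return float(sum(d.sum() for _, d in self._data.values()))

    def last_covered_before(self, chrom: str, pos: int, min_depth: float = 1.0) -> int | None:
        """Greatest position < ``pos`` with depth >= ``min_depth``, or None."""
        if chrom not in self._data:
            return None
        p, d = self._data[chrom]
        hi = np.searchsorted(p, pos, side="left")
        idx = np.nonzero(d[:hi] >= min_depth)[0]
        return int(p[idx[-1]]) if idx.size else None

    def first_covered_after(self, chrom: str, pos: int, min_depth: float = 1.0) -> int | None:
        """Least position > ``pos`` with depth >= ``min_depth``, or None."""
        if chrom not in self._data:
            return None
        p, d = self._data[chrom]
        lo = np.searchsorted(p, pos, side="right")
        idx = np.nonzero(d[lo:] >= min_depth)[0]
        return int(p[lo + idx[0]]) if idx.size else None

    def max_covered(self, chrom: str, min_depth: float = 1.0) -> int | None:
        return self.last_covered_before(chrom, np.iinfo(np.int64).max, min_depth)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            for c in self._data
        )


@dataclass
class GeneCountTable:
    """Raw per-gene read counts for the two bulks, plus library sizes."""

    counts: dict[str, tuple[int, int]]  # gene_id -> (normal, mutant)
    n_library_size: int
    m_library_size: int

    def __post_init__(self) -> None:
        for gene, (n, m) in self.counts.items():
            if n < 0 or m < 0:
                raise ValueError(f"negative count for gene {gene}")


@dataclass(frozen=True)
class PositiveSite:
    """A site whose allele pattern marks linkage to the causative locus:
    Mo17-origin allele at fraction >= 0.5 in the normal bulk, and the mutant
    bulk effectively pure B73."""

    site: PooledSiteCall
    mo17_frac_normal: float
    mutant_alt_frac: float


@dataclass(frozen=True)
class WindowCount:
    chrom: str
    start: int
    end: int
    count: int


@dataclass(frozen=True)
class LinkagePeak:
    chrom: str
    peak_window: WindowCount
    region_start: int
    region_end: int
    n_ties: int = 1


@dataclass(frozen=True)
class LinkageGap:
    chrom: str
    start: int
    end: int
    n_zero_windows: int


@dataclass
class ExonDepth:
    """Accumulated (D) and normalized (1e9*D/(L*D_a)) depth for one exon."""

    exon: ExonRecord
    D: float
    norm: float | None = None


@dataclass(frozen=True)
class DeletionCall:
    """A called deletion reported as its flanking breakpoints.

    ``left_bp``/``right_bp`` are the last and first covered positions outside
    the deletion; the deleted length is ``right_bp - left_bp - 1``.
    """

    chrom: str
    left_bp: int
    right_bp: int
    length: int
    deleted_exons: tuple[str, ...]
    genes: tuple[str, ...]
    provenance: str = "exome_depth"
    left_truncated: bool = False
    right_truncated: bool = False

    def __post_init__(self) -> None:
        if self.left_bp >= self.right_bp:
            raise ValueError("left breakpoint must be < right breakpoint")
        if self.length != self.right_bp - self.left_bp - 1:
            raise ValueError("length inconsistent with breakpoints")


@dataclass(frozen=True)
class MutationKey:
    """Canonical identity of one mutation for exact occurrence counting.

    Deleted exons are keyed by annotation identity (exon_id); SNPs and small
    indels by coordinates and alleles after canonicalization.
    """

    kind: str  # deleted_exon | small_indel | snp
    chrom: str
    start: int
    end: int
    ref: str = ""
    alt: str = ""
    exon_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deleted_exon", "small_indel", "snp"):
            raise ValueError(f"unknown mutation kind: {self.kind!r}")
        if self.start > self.end:
            raise ValueError("mutation start > end")


@dataclass
class MutantDataset:
    """Everything the pipeline knows about one mutant line."""

    mutant_id: str
    mutations: list[MutationKey] = field(default_factory=list)
    variant_calls: list[PooledSiteCall] | None = None
    exon_depths: list[ExonDepth] | None = None
    gene_counts: GeneCountTable | None = None


@dataclass
class GeneExpression:
    """Per-gene normalized bulk expression and the pseudocounted fold change
    fc = n_norm / (m_norm + 0.05)."""

    gene_id: str
    n_norm: float
    m_norm: float
    fc: float | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass(frozen=True)
class Candidate:
    """One entry of a candidate report: a deletion call or a dropout gene."""

    label: str
    chrom: str
    start: int
    end: int
    evidence: str  # deletion_in_gap | deletion_in_peak | expression_dropout | deletion_outside_peak
    distance_to_peak: float
    fc: float | None = None
    deletion: DeletionCall | None = None


@dataclass
class CandidateReport:
    mutant_id: str
    peak: LinkagePeak | None
    gaps: list[LinkageGap]
    candidates: list[Candidate]
    note: str = ""
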