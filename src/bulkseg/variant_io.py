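"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* Internal coordinates are always 1-based inclusive.
* BED and bedGraph are 0-based half-open on disk and converted here.
* The canonical variant table is a TSV with columns
  ``chrom pos ref alt n_ref n_alt m_ref m_alt is_indel``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import DeletionCall, DepthTrack, ExonRecord, GeneCountTable, LinkageGap, PooledSiteCall, WindowCount

log = logging.getLogger(__name__)

VARSCAN_COLUMNS = ["chrom", "pos", "ref", "alt", "n_ref", "n_alt", "m_ref", "m_alt"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# pooled variant calls
# ---------------------------------------------------------------------------

def read_pooled_variants(
    path: str | Path,
    format: str = "varscan_tab",
    *,
    multiallelic: str = "skip",
    normal_sample: str | None = None,
    mutant_sample: str | None = None,
) -> list[PooledSiteCall]:
    """Read pooled variant calls for the normal and mutant bulks.

    Parameters
    ----------
    format
        ``"vcf"`` — a two-sample VCF with AD-style allele depths, normal
        sample first, mutant second; or ``"varscan_tab"`` — a TSV with the
        columns ``chrom pos ref alt n_ref n_alt m_ref m_alt`` (an optional
        ``is_indel`` column is honoured).
    multiallelic
        ``"skip"`` (default, logged) or ``"split"`` rows with several ALT
        alleles.  The positive-site definition requires exactly two alleles,
        so split records are only useful for bookkeeping.
    normal_sample, mutant_sample
        When given for VCF input, the first/second sample names must match;
        a mismatch is an error, never a silent swap.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "varscan_tab":
        return _read_varscan_tab(path)
    if format == "vcf":
        return _read_vcf(path, multiallelic, normal_sample, mutant_sample)
    raise ValueError(f"unknown variant format: {format!r}")


def _read_varscan_tab(path: Path) -> list[PooledSiteCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARSCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_indel = "is_indel" in df.columns
    calls = []
    for row in df.itertuples(index=False):
        is_indel = bool(getattr(row, "is_indel")) if has_indel else (
            len(str(row.ref)) != len(str(row.alt))
        )
        calls.append(
            PooledSiteCall(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                n_ref=int(row.n_ref),
                n_alt=int(row.n_alt),
                m_ref=int(row.m_ref),
                m_alt=int(row.m_alt),
                is_indel=is_indel,
            )
        )
    _warn_if_unsorted(calls, path)
    return calls


def _read_vcf(
    path: Path,
    multiallelic: str,
    normal_sample: str | None,
    mutant_sample: str | None,
) -> list[PooledSiteCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 samples (normal, mutant), found {samples}"
        )
    if normal_sample is not None and samples[0] != normal_sample:
        raise FormatError(
            f"{path}: first sample is {samples[0]!r}, expected normal sample {normal_sample!r}"
        )
    if mutant_sample is not None and samples[1] != mutant_sample:
        raise FormatError(
            f"{path}: second sample is {samples[1]!r}, expected mutant sample {mutant_sample!r}"
        )
    calls: list[PooledSiteCall] = []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"{path}: no AD field at {var.CHROM}:{var.POS}")
        if len(alts) != 1:
            if multiallelic == "skip":
                n_skipped += 1
                continue
            if multiallelic != "split":
                raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
        for ai, alt in enumerate(alts, start=1):
            if len(alts) > 1 and multiallelic == "skip":
                break
            calls.append(
                PooledSiteCall(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref_allele=var.REF,
                    alt_allele=alt,
                    n_ref=max(int(ad[0][0]), 0),
                    n_alt=max(int(ad[0][ai]), 0),
                    m_ref=max(int(ad[1][0]), 0),
                    m_alt=max(int(ad[1][ai]), 0),
                    is_indel=len(var.REF) != len(alt),
                )
            )
    if n_skipped:
        log.info("%s: skipped %d multiallelic rows", path, n_skipped)
    _warn_if_unsorted(calls, path)
    return calls


def _warn_if_unsorted(calls: Sequence[PooledSiteCall], path: Path) -> None:
    last: tuple[str, int] | None = None
    for c in calls:
        key = (c.chrom, c.pos)
        if last is not None and key[0] == last[0] and key[1] < last[1]:
            log.warning("%s: input not coordinate-sorted; downstream steps sort", path)
            return
        last = key


def write_pooled_variants(calls: Iterable[PooledSiteCall], path: str | Path) -> None:
    """Write calls as the canonical VarScan-style TSV (round-trips exactly)."""
    rows = [
        (c.chrom, c.pos, c.ref_allele, c.alt_allele, c.n_ref, c.n_alt, c.m_ref, c.m_alt, int(c.is_indel))
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=VARSCAN_COLUMNS + ["is_indel"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# exon annotation
# ---------------------------------------------------------------------------

def read_exon_annotation(path: str | Path, format: str = "bed") -> list[ExonRecord]:
    """Read exon annotation from BED (0-based half-open) or GFF3.

    BED names are exon IDs; the gene ID is the name up to its last ``.``
    (``gX.1`` -> gene ``gX``).  GFF3 exon features take their gene from a
    ``gene_id`` attribute or the ``Parent``; exon IDs absent from the file
    are synthesized as ``gene_id.N`` in input order.  Exon IDs must be unique
    within a file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        records = _read_exon_bed(path)
    elif format == "gff3":
        records = _read_exon_gff3(path)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.exon_id in seen:
            raise FormatError(f"{path}: duplicate exon_id {rec.exon_id!r}")
        seen.add(rec.exon_id)
    return records


def _read_exon_bed(path: Path) -> list[ExonRecord]:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     dtype={0: str}, engine="python")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        start0, end0 = int(row[1]), int(row[2])
        if end0 < start0:
            raise FormatError(f"{path}: interval end {end0} < start {start0}")
        name = str(row[3]) if df.shape[1] > 3 and not pd.isna(row[3]) else f"exon.{i + 1}"
        gene = name.rsplit(".", 1)[0] if "." in name else name
        strand = row[5] if df.shape[1] > 5 and row[5] in ("+", "-") else "+"
        records.append(
            ExonRecord(gene_id=gene, exon_id=name, chrom=str(row[0]),
                       start=start0 + 1, end=end0, strand=strand)
        )
    return records


def _read_exon_gff3(path: Path) -> list[ExonRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    counters: dict[str, int] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise FormatError(f"{path}: exon end {feat.end} < start {feat.start}")
        gene = (
            feat.attributes.get("gene_id", [None])[0]
            or feat.attributes.get("Parent", [None])[0]
            or "unknown_gene"
        )
        exon_id = feat.attributes.get("exon_id", [None])[0] or feat.attributes.get("ID", [None])[0]
        if exon_id is None:
            counters[gene] = counters.get(gene, 0) + 1
            exon_id = f"{gene}.{counters[gene]}"
        records.append(
            ExonRecord(gene_id=gene, exon_id=exon_id, chrom=feat.seqid,
                       start=feat.start, end=feat.end,
                       strand=feat.strand if feat.strand in ("+", "-") else "+")
        )
    return records


def write_exon_bed(exons: Iterable[ExonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in exons:
            fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.exon_id}\t0\t{e.strand}\n")


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

def read_depth_track(path: str | Path, format: str = "samtools_depth_tsv") -> DepthTrack:
    """Read a per-base depth track.

    ``samtools_depth_tsv`` rows are ``chrom pos depth`` (1-based);
    ``bedgraph`` rows are ``chrom start end depth`` (0-based half-open).
    Positions not listed have depth 0.  Negative depths are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    track = DepthTrack()
    if format == "samtools_depth_tsv":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "pos", "depth"], dtype={"chrom": str})
        if len(df) and (df["depth"] < 0).any():
            raise FormatError(f"{path}: negative depth")
        for chrom, grp in df.groupby("chrom", sort=False):
            track.add_positions(str(chrom), grp["pos"].to_numpy(np.int64),
                                grp["depth"].to_numpy(np.float64))
    elif format == "bedgraph":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "depth"], dtype={"chrom": str})
        if len(df) and (df["depth"] < 0).any():
            raise FormatError(f"{path}: negative depth")
        if len(df) and (df["end"] <= df["start"]).any():
            raise FormatError(f"{path}: empty bedGraph interval")
        for chrom, grp in df[df["depth"] > 0].groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(np.int64) + 1
            ends = grp["end"].to_numpy(np.int64)
            lens = ends - starts + 1
            offsets = np.arange(int(lens.sum())) - np.repeat(
                np.cumsum(lens) - lens, lens
            )
            pos = np.repeat(starts, lens) + offsets
            dep = np.repeat(grp["depth"].to_numpy(np.float64), lens)
            track.add_positions(str(chrom), pos, dep)
    else:
        raise ValueError(f"unknown depth format: {format!r}")
    return track


def write_depth_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Write a DepthTrack as bedGraph, merging runs of equal depth."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos = track.positions(chrom)
            dep = track.depths(chrom)
            if pos.size == 0:
                continue
            # run boundaries: position jumps or depth changes
            brk = np.nonzero((np.diff(pos) != 1) | (np.diff(dep) != 0))[0]
            starts = np.concatenate([[0], brk + 1])
            ends = np.concatenate([brk, [pos.size - 1]])
            for s, e in zip(starts, ends):
                d = dep[s]
                val = int(d) if float(d).is_integer() else float(d)
                fh.write(f"{chrom}\t{pos[s] - 1}\t{pos[e]}\t{val}\n")


# ---------------------------------------------------------------------------
# gene counts
# ---------------------------------------------------------------------------

def read_gene_counts(path: str | Path) -> GeneCountTable:
    """Read a TSV ``gene_id n_count m_count``; library sizes may be supplied
    as a ``#library_sizes n m`` comment line, else default to column sums."""
    path = Path(path)
    lib_n = lib_m = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#library_sizes"):
        _, lib_n, lib_m = first.split()
        lib_n, lib_m = int(lib_n), int(lib_m)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    counts = {
        str(r.gene_id): (int(r.n_count), int(r.m_count))
        for r in df.itertuples(index=False)
    }
    if lib_n is None:
        lib_n = sum(n for n, _ in counts.values())
        lib_m = sum(m for _, m in counts.values())
    return GeneCountTable(counts=counts, n_library_size=lib_n, m_library_size=lib_m)


def write_gene_counts(table: GeneCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_sizes {table.n_library_size} {table.m_library_size}\n")
        fh.write("gene_id\tn_count\tm_count\n")
        for gene, (n, m) in table.counts.items():
            fh.write(f"{gene}\t{n}\t{m}\n")


# ---------------------------------------------------------------------------
# generic interval output
# ---------------------------------------------------------------------------

def _interval_fields(rec) -> tuple[str, int, int, str, object]:
    if isinstance(rec, WindowCount):
        return rec.chrom, rec.start, rec.end, ".", rec.count
    if isinstance(rec, LinkageGap):
        return rec.chrom, rec.start, rec.end, "gap", rec.n_zero_windows
    if isinstance(rec, DeletionCall):
        return rec.chrom, rec.left_bp, rec.right_bp, ",".join(rec.deleted_exons) or rec.provenance, rec.length
    chrom, start, end = rec.chrom, rec.start, rec.end
    return chrom, start, end, getattr(rec, "label", "."), getattr(rec, "score", 0)


def write_intervals(records: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write windows / gaps / deletion calls as TSV (1-based inclusive, with
    a header naming the convention) or BED (0-based half-open)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#coordinates: 1-based inclusive\n")
            fh.write("chrom\tstart\tend\tlabel\tscore\n")
            for rec in records:
                chrom, start, end, label, score = _interval_fields(rec)
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\t{score}\n")
    elif format == "bed":
        with open(path, "w") as fh:
            for rec in records:
                chrom, start, end, label, score = _interval_fields(rec)
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{label}\t{score}\n")
    else:
        raise ValueError(f"unknown interval format: {format!r}")


def read_intervals_tsv(path: str | Path) -> pd.DataFrame:
    """Read back an interval TSV written by :func:`write_intervals`."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "label": str})
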