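"""Cross-mutant background filtering.

All mutants of an irradiated population share the residual genetic drift of
their common inbred stock relative to the reference assembly.  Two mutants
carrying an *identical* induced deletion is essentially impossible, so any
mutation observed in two or more mutants must be background and cannot be
causative.  This module canonicalizes mutation records into exact-match
keys and discards every key seen in >= 2 distinct mutants.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .types import MutantDataset, MutationKey

log = logging.getLogger(__name__)


def canonicalize_mutation(
    record: Mapping | MutationKey,
    reference: Mapping[str, str] | None = None,
) -> MutationKey:
    """Build the canonical exact-match key for a raw mutation record.

    SNP alleles are upper-cased.  Indels are left-normalized when reference
    context is available (shifted to the smallest start that yields the same
    edited sequence, VCF-style with a retained anchor base); without context
    they compare as given, with a one-time warning.  Deleted exons are keyed
    by exon_id — annotation identity — since the depth caller emits whole
    annotated exons.
    """
    if isinstance(record, MutationKey):
        rec = {
            "kind": record.kind, "chrom": record.chrom, "start": record.start,
            "end": record.end, "ref": record.ref, "alt": record.alt,
            "exon_id": record.exon_id,
        }
    else:
        rec = dict(record)
    kind = rec.get("kind")
    if kind not in ("deleted_exon", "small_indel", "snp"):
        raise ValueError(f"unknown mutation kind: {kind!r}")
    chrom = str(rec["chrom"])
    if kind == "deleted_exon":
        return MutationKey(kind=kind, chrom=chrom, start=int(rec["start"]),
                           end=int(rec["end"]), exon_id=str(rec["exon_id"]))
    ref = str(rec.get("ref", "")).upper()
    alt = str(rec.get("alt", "")).upper()
    start = int(rec["start"])
    if kind == "snp":
        return MutationKey(kind=kind, chrom=chrom, start=start, end=start,
                           ref=ref, alt=alt)
    # small indel
    if reference is not None and chrom in reference:
        start, ref, alt = _left_normalize(reference[chrom], start, ref, alt)
    else:
        _warn_no_context()
    return MutationKey(kind=kind, chrom=chrom, start=start,
                       end=start + len(ref) - 1, ref=ref, alt=alt)


_warned = False


def _warn_no_context() -> None:
    global _warned
    if not _warned:
        log.warning("no reference context supplied; indel keys compare as given")
        _warned = True


def _left_normalize(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a (pos, ref, alt) indel on a 1-based reference sequence.

    Standard variant normalization: repeatedly trim a shared trailing base
    (extending leftward with the preceding reference base when one allele
    would become empty), then trim shared leading bases while both alleles
    keep an anchor.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
                continue
            if pos > 1:
                base = seq[pos - 2].upper()
                ref = base + ref[:-1]
                alt = base + alt[:-1]
                pos -= 1
                continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class SharedMutation:
    key: MutationKey
    mutant_ids: tuple[str, ...]


@dataclass
class FilterResult:
    """Per-mutant cohort-unique mutations plus the shared-mutation report."""

    unique: dict[str, list[MutationKey]]
    shared: list[SharedMutation]
    n_within_duplicates: dict[str, int] = field(default_factory=dict)


def filter_shared_mutations(
    cohort: Sequence[MutantDataset],
    min_occurrence_to_discard: int = 2,
) -> FilterResult:
    """Discard every mutation key observed in >= ``min_occurrence_to_discard``
    distinct mutants.

    Occurrence counts distinct mutants, not records: duplicate records
    within one mutant deduplicate first and count once.  The remaining
    per-mutant lists contain only cohort-unique mutations; order within each
    mutant is preserved.
    """
    ids = [m.mutant_id for m in cohort]
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate mutant_id(s): {dupes}")
    deduped: dict[str, list[MutationKey]] = {}
    n_within: dict[str, int] = {}
    for m in cohort:
        seen: set[MutationKey] = set()
        kept = []
        for key in m.mutations:
            if key not in seen:
                seen.add(key)
                kept.append(key)
        deduped[m.mutant_id] = kept
        n_within[m.mutant_id] = len(m.mutations) - len(kept)
    occurrence: Counter[MutationKey] = Counter()
    for keys in deduped.values():
        occurrence.update(keys)
    shared_keys = {k for k, c in occurrence.items() if c >= min_occurrence_to_discard}
    unique = {
        mid: [k for k in keys if k not in shared_keys]
        for mid, keys in deduped.items()
    }
    shared = sorted(
        (
            SharedMutation(
                key=k,
                mutant_ids=tuple(sorted(mid for mid, keys in deduped.items() if k in set(keys))),
            )
            for k in shared_keys
        ),
        key=lambda s: (s.key.chrom, s.key.start, s.key.kind, s.key.exon_id, s.key.ref, s.key.alt),
    )
    return FilterResult(unique=unique, shared=shared, n_within_duplicates=n_within)
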