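"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the study design end to end with no external data:
an F2 population from a cross of a reference-background deletion mutant to
a polymorphic mapper line (B73 mutant x Mo17), phenotype-bulked pools,
pooled RNA-seq read counts at biallelic marker sites, capture-style exome
depth tracks with a planted deletion, per-gene bulk expression with dropout
genes, and multi-mutant cohorts sharing background mutations.

Recombination follows the Haldane map function without interference; each
plant receives two independent gametes simulated as a Markov chain along
each chromosome.  Plants contribute equally to pooled allele frequencies
and sequencing noise is binomial given the pool frequency, so the key
expectations stay closed-form: at the causative marker the normal bulk
(1 AA : 2 Aa) has Mo17-allele fraction 2/3 and the mutant bulk 0.

One master seed drives everything; each stage derives an independent
stream from a fixed label, so adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import (
    DepthTrack,
    ExonRecord,
    GeneCountTable,
    MutantDataset,
    MutationKey,
    PooledSiteCall,
)

# fixed labels for independent sub-streams of the master seed
_STREAMS = {
    "markers": 1,
    "genotypes": 2,
    "pools": 3,
    "reads": 4,
    "exome": 5,
    "counts": 6,
    "cohort": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class ExonSpec:
    """Synthetic annotation layout: genes tiled across a region, each with
    ``exons_per_gene`` exons of ``exon_length`` bp separated by introns."""

    exons_per_gene: int = 6
    exon_length: int = 200
    intron_length: int = 800
    gene_spacing: int = 5_000
    capture_flank: int = 100  # captured intron flank on each side of an exon
    region_pad: int = 300_000  # annotated margin beyond the planted deletion
    n_background_genes: int = 30  # negative-control genes on another chromosome

    @property
    def gene_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )

    @property
    def gene_stride(self) -> int:
        return self.gene_length + self.gene_spacing


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the defaults are the study conditions.

    Pools of 30 plants per phenotype class (the study pooled 21-30), mean
    pooled read depth 20 per marker site, per-read miscall rate 0.002, a
    uniform 1 cM/Mb genetic map, markers averaging one per 50 kb, and a
    1 Mb causative deletion centred on the causative locus.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i}", 50_000_000) for i in range(1, 11)
    )
    marker_spacing: int = 50_000
    causative: tuple[str, int] = ("chr5", 25_000_000)
    # breakpoint convention: deleted bases lie strictly between left and right
    deletion: tuple[str, int, int] | None = ("chr5", 24_500_000, 25_500_001)
    exons: ExonSpec = field(default_factory=ExonSpec)
    pool_size_normal: int = 30
    pool_size_mutant: int = 30
    n_plants: int = 200
    depth_lambda: float = 20.0
    error_rate: float = 0.002
    cm_per_mb: float = 1.0
    misclassification_rate: float = 0.0
    expression_mean: float = 100.0
    n_background_shared: int = 5
    n_mutants: int = 3
    n_incidental_deletions: int = 1

    def __post_init__(self) -> None:
        if self.pool_size_normal < 1 or self.pool_size_mutant < 1:
            raise ValueError("pool sizes must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        lengths = dict(self.chromosomes)
        chrom, pos = self.causative
        if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
            raise ValueError("causative locus outside chromosome bounds")
        if self.deletion is not None:
            dchrom, left, right = self.deletion
            if dchrom not in lengths or left >= right or right > lengths[dchrom]:
                raise ValueError("invalid deletion interval")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class F2Genotypes:
    """Marker positions and per-plant Mo17-allele dosage (0/1/2) matrices."""

    markers: dict[str, np.ndarray]          # chrom -> sorted positions
    dosage: dict[str, np.ndarray]           # chrom -> (n_plants, n_markers) int8
    causative_index: tuple[str, int]        # chrom, column of the causative marker

    @property
    def n_plants(self) -> int:
        return next(iter(self.dosage.values())).shape[0]

    def causative_dosage(self) -> np.ndarray:
        chrom, idx = self.causative_index
        return self.dosage[chrom][:, idx]


@dataclass
class TruthRecord:
    """Planted ground truth, consistent with the emitted data by construction."""

    causative: tuple[str, int]
    deletion: tuple[str, int, int] | None
    deleted_exon_ids: tuple[str, ...] = ()
    dropout_gene_ids: tuple[str, ...] = ()
    incidental_deleted_exon_ids: tuple[str, ...] = ()
    shared_background: tuple[MutationKey, ...] = ()
    per_mutant_deletions: dict[str, tuple[str, int, int]] = field(default_factory=dict)


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_marker_positions(config: SimConfig) -> dict[str, np.ndarray]:
    """One marker per ``marker_spacing`` bin, uniformly placed within it.

    Mean spacing equals ``marker_spacing``; the irregular placement mirrors
    real inter-line SNP markers, which never sit on a lattice.  Markers
    inside the planted deletion are retained here (genotypes exist there);
    the read simulator drops them, since the deletion removed the template.
    """
    rng = _rng(config.seed, "markers")
    markers = {}
    for chrom, length in config.chromosomes:
        n_bins = length // config.marker_spacing
        offsets = rng.integers(1, config.marker_spacing + 1, size=n_bins)
        pos = np.arange(n_bins, dtype=np.int64) * config.marker_spacing + offsets
        markers[chrom] = pos
    # guarantee a marker exactly at the causative locus so selection and the
    # closed-form pool expectations are anchored there
    cchrom, cpos = config.causative
    pos = markers[cchrom]
    i = int(np.argmin(np.abs(pos - cpos)))
    pos = pos.copy()
    pos[i] = cpos
    markers[cchrom] = np.unique(pos)
    return markers


def simulate_f2_genotypes(
    config: SimConfig,
    markers: dict[str, np.ndarray] | None = None,
) -> F2Genotypes:
    """Simulate F2 plants as pairs of independent recombinant gametes.

    Each gamete is a Markov chain along a chromosome: the allele at the
    first marker is Bernoulli(1/2) and switches between adjacent markers
    with the Haldane probability for their map distance
    (``cm_per_mb * Mb``).  With ``cm_per_mb = 0`` gametes are
    non-recombinant and genotypes are 1:2:1 at every marker.
    """
    if markers is None:
        markers = simulate_marker_positions(config)
    rng = _rng(config.seed, "genotypes")
    n = config.n_plants
    dosage: dict[str, np.ndarray] = {}
    for chrom, _length in config.chromosomes:
        pos = markers[chrom]
        m = pos.size
        d_cm = np.diff(pos) / 1e6 * config.cm_per_mb
        r = _haldane_r(d_cm)
        first = rng.integers(0, 2, size=(2 * n, 1), dtype=np.int8)
        if m > 1:
            rec = (rng.random((2 * n, m - 1)) < r[None, :]).astype(np.int8)
            switches = np.cumsum(rec, axis=1, dtype=np.int32) % 2
            gametes = (first + np.concatenate(
                [np.zeros((2 * n, 1), dtype=np.int32), switches], axis=1
            )) % 2
        else:
            gametes = first.astype(np.int32)
        dosage[chrom] = (gametes[:n] + gametes[n:]).astype(np.int8)
    cchrom, cpos = config.causative
    cidx = int(np.searchsorted(markers[cchrom], cpos))
    return F2Genotypes(markers=markers, dosage=dosage, causative_index=(cchrom, cidx))


def select_pools(
    genotypes: F2Genotypes, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the mutant pool (homozygous reference at the causative locus)
    and the normal pool (everything else, in realized AA:Aa proportions)."""
    rng = _rng(config.seed, "pools")
    dosage = genotypes.causative_dosage()
    mutant_plants = np.nonzero(dosage == 0)[0]
    normal_plants = np.nonzero(dosage > 0)[0]
    if mutant_plants.size < config.pool_size_mutant:
        raise ValueError(
            f"only {mutant_plants.size} mutant (homozygous-reference) plants for a "
            f"pool of {config.pool_size_mutant}; simulate a larger population"
        )
    if normal_plants.size < config.pool_size_normal:
        raise ValueError("not enough normal plants; simulate a larger population")
    mutant_pool = rng.choice(mutant_plants, size=config.pool_size_mutant, replace=False)
    normal_pool = rng.choice(normal_plants, size=config.pool_size_normal, replace=False)
    if config.misclassification_rate > 0:
        swap = rng.random(config.pool_size_mutant) < config.misclassification_rate
        if swap.any():
            repl = rng.choice(normal_plants, size=int(swap.sum()), replace=False)
            mutant_pool = mutant_pool.copy()
            mutant_pool[np.nonzero(swap)[0]] = repl
    return normal_pool, mutant_pool


def simulate_pooled_reads(
    genotypes: F2Genotypes,
    config: SimConfig,
    pools: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[PooledSiteCall]:
    """Emit pooled variant calls at every marker outside the deletion.

    Per site and pool, total depth is Poisson(``depth_lambda``); each read
    draws the Mo17 allele with the pool frequency, flipped with probability
    ``error_rate``.  Markers strictly inside the planted deletion produce no
    calls: the mutant bulk has no template there, and an expressed-marker
    -free region yields no variant rows at all.
    """
    if pools is None:
        pools = select_pools(genotypes, config)
    normal_pool, mutant_pool = pools
    rng = _rng(config.seed, "reads")
    e = config.error_rate
    calls: list[PooledSiteCall] = []
    deletion = config.deletion
    for chrom, _length in config.chromosomes:
        pos = genotypes.markers[chrom]
        dos = genotypes.dosage[chrom]
        keep = np.ones(pos.size, dtype=bool)
        if deletion is not None and deletion[0] == chrom:
            keep = ~((pos > deletion[1]) & (pos < deletion[2]))
        f_n = dos[normal_pool].sum(axis=0) / (2 * normal_pool.size)
        f_m = dos[mutant_pool].sum(axis=0) / (2 * mutant_pool.size)
        depth_n = rng.poisson(config.depth_lambda, size=pos.size)
        depth_m = rng.poisson(config.depth_lambda, size=pos.size)
        p_n = f_n * (1 - e) + (1 - f_n) * e
        p_m = f_m * (1 - e) + (1 - f_m) * e
        alt_n = rng.binomial(depth_n, p_n)
        alt_m = rng.binomial(depth_m, p_m)
        for i in np.nonzero(keep)[0]:
            calls.append(
                PooledSiteCall(
                    chrom=chrom, pos=int(pos[i]), ref_allele="A", alt_allele="G",
                    n_ref=int(depth_n[i] - alt_n[i]), n_alt=int(alt_n[i]),
                    m_ref=int(depth_m[i] - alt_m[i]), m_alt=int(alt_m[i]),
                )
            )
    return calls


def synthesize_exon_annotation(config: SimConfig) -> list[ExonRecord]:
    """Tile genes over the deletion neighbourhood plus a background block.

    Genes cover ``deletion +/- region_pad`` on the deletion chromosome (or a
    block around the causative locus when no deletion is planted), with
    ``n_background_genes`` negative-control genes on the first other
    chromosome.  Gene IDs encode the chromosome; exon IDs are ``gene.N``.
    """
    spec = config.exons
    if config.deletion is not None:
        chrom, left, right = config.deletion
        region_start = max(1, left - spec.region_pad)
        region_end = right + spec.region_pad
    else:
        chrom, cpos = config.causative
        region_start = max(1, cpos - spec.region_pad)
        region_end = cpos + spec.region_pad
    exons: list[ExonRecord] = []

    def add_gene(gene_id: str, gchrom: str, gstart: int) -> None:
        p = gstart
        for j in range(1, spec.exons_per_gene + 1):
            exons.append(
                ExonRecord(gene_id=gene_id, exon_id=f"{gene_id}.{j}", chrom=gchrom,
                           start=p, end=p + spec.exon_length - 1)
            )
            p += spec.exon_length + spec.intron_length

    i = 0
    g = region_start
    while g + spec.gene_length - 1 <= region_end:
        i += 1
        add_gene(f"g{chrom}_{i:04d}", chrom, g)
        g += spec.gene_stride
    bg_chrom = next(c for c, _ in config.chromosomes if c != chrom)
    g = 1_000_000
    for i in range(1, spec.n_background_genes + 1):
        add_gene(f"g{bg_chrom}_{i:04d}", bg_chrom, g)
        g += spec.gene_stride
    return exons


def simulate_exome_depths(
    config: SimConfig,
    exons: list[ExonRecord] | None = None,
) -> tuple[DepthTrack, DepthTrack, list[ExonRecord], TruthRecord]:
    """Capture-style control and mutant depth tracks with the planted
    deletion zeroed out in the mutant.

    Per-base depth is Poisson(``depth_lambda``) over each exon plus its
    captured flank and 0 elsewhere.  The mutant track is forced to 0
    strictly inside the deletion, and ``n_incidental_deletions`` background
    exons are knocked out as non-causative decoys.  Truth lists every exon
    whose body lies fully inside the deletion.
    """
    if exons is None:
        exons = synthesize_exon_annotation(config)
    rng = _rng(config.seed, "exome")
    spec = config.exons
    deletion = config.deletion
    bg_exons = [e for e in exons if deletion is None or e.chrom != deletion[0]]
    incidental: list[ExonRecord] = []
    if config.n_incidental_deletions > 0 and bg_exons:
        idx = rng.choice(len(bg_exons), size=min(config.n_incidental_deletions, len(bg_exons)),
                         replace=False)
        incidental = [bg_exons[int(i)] for i in np.sort(idx)]
    incidental_ids = {e.exon_id for e in incidental}
    deleted_ids: list[str] = []
    acc: dict[str, tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]] = {}
    for e in exons:
        lo = max(1, e.start - spec.capture_flank)
        hi = e.end + spec.capture_flank
        pos = np.arange(lo, hi + 1, dtype=np.int64)
        dep_c = rng.poisson(config.depth_lambda, pos.size).astype(np.float64)
        dep_m = rng.poisson(config.depth_lambda, pos.size).astype(np.float64)
        if deletion is not None and e.chrom == deletion[0]:
            inside = (pos > deletion[1]) & (pos < deletion[2])
            dep_m[inside] = 0.0
            if e.start > deletion[1] and e.end < deletion[2]:
                deleted_ids.append(e.exon_id)
        if e.exon_id in incidental_ids:
            body = (pos >= e.start) & (pos <= e.end)
            dep_m[body] = 0.0
        p, c, m = acc.setdefault(e.chrom, ([], [], []))
        p.append(pos)
        c.append(dep_c)
        m.append(dep_m)
    control = DepthTrack()
    mutant = DepthTrack()
    for chrom, (p, c, m) in acc.items():
        control.add_positions(chrom, np.concatenate(p), np.concatenate(c))
        mutant.add_positions(chrom, np.concatenate(p), np.concatenate(m))
    if deletion is not None and not deleted_ids:
        import logging

        logging.getLogger(__name__).warning(
            "planted deletion overlaps no exon body; undetectable by design"
        )
    gene_span: dict[str, tuple[str, int, int]] = {}
    for e in exons:
        c, lo_, hi_ = gene_span.get(e.gene_id, (e.chrom, e.start, e.end))
        gene_span[e.gene_id] = (c, min(lo_, e.start), max(hi_, e.end))
    dropout = tuple(
        g for g, (c, lo_, hi_) in gene_span.items()
        if deletion is not None and c == deletion[0]
        and lo_ > deletion[1] and hi_ < deletion[2]
    )
    truth = TruthRecord(
        causative=config.causative,
        deletion=deletion,
        deleted_exon_ids=tuple(deleted_ids),
        dropout_gene_ids=dropout,
        incidental_deleted_exon_ids=tuple(e.exon_id for e in incidental),
    )
    return control, mutant, exons, truth


def simulate_gene_counts(
    config: SimConfig,
    exons: list[ExonRecord],
    truth: TruthRecord,
) -> tuple[GeneCountTable, dict[str, tuple[str, int, int]]]:
    """Per-gene bulk read counts: Poisson(``expression_mean``) in each bulk,
    with genes fully inside the deletion silenced in the mutant bulk and
    partially deleted genes reduced proportionally to surviving exons."""
    rng = _rng(config.seed, "counts")
    spans: dict[str, tuple[str, int, int]] = {}
    exon_count: dict[str, int] = {}
    deleted_count: dict[str, int] = {}
    deleted_ids = set(truth.deleted_exon_ids)
    for e in exons:
        c, lo, hi = spans.get(e.gene_id, (e.chrom, e.start, e.end))
        spans[e.gene_id] = (c, min(lo, e.start), max(hi, e.end))
        exon_count[e.gene_id] = exon_count.get(e.gene_id, 0) + 1
        if e.exon_id in deleted_ids:
            deleted_count[e.gene_id] = deleted_count.get(e.gene_id, 0) + 1
    counts: dict[str, tuple[int, int]] = {}
    for gene in spans:
        n = int(rng.poisson(config.expression_mean))
        retained = 1.0 - deleted_count.get(gene, 0) / exon_count[gene]
        m = int(rng.poisson(config.expression_mean * retained)) if retained > 0 else 0
        counts[gene] = (n, m)
    table = GeneCountTable(
        counts=counts,
        n_library_size=max(1, sum(n for n, _ in counts.values())),
        m_library_size=max(1, sum(m for _, m in counts.values())),
    )
    return table, spans


@dataclass
class SimulatedDataset:
    """One mutant's complete synthetic inputs plus ground truth."""

    config: SimConfig
    calls: list[PooledSiteCall]
    control_track: DepthTrack
    mutant_track: DepthTrack
    exons: list[ExonRecord]
    gene_counts: GeneCountTable
    gene_spans: dict[str, tuple[str, int, int]]
    truth: TruthRecord


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run every generator stage for one mutant under one master seed."""
    genotypes = simulate_f2_genotypes(config)
    calls = simulate_pooled_reads(genotypes, config)
    control, mutant, exons, truth = simulate_exome_depths(config)
    table, spans = simulate_gene_counts(config, exons, truth)
    return SimulatedDataset(
        config=config, calls=calls, control_track=control, mutant_track=mutant,
        exons=exons, gene_counts=table, gene_spans=spans, truth=truth,
    )


def simulate_cohort(config: SimConfig) -> tuple[list[MutantDataset], TruthRecord]:
    """A cohort of mutants with distinct causative deletions plus shared
    background absent exons (for the occurrence filter).

    Each mutant's mutation list holds deleted-exon keys for its own
    causative deletion and for the ``n_background_shared`` background exons
    planted in every mutant; deterministic given the master seed.
    """
    rng = _rng(config.seed, "cohort")
    exons = synthesize_exon_annotation(config)
    bg_chrom_exons = [e for e in exons if e.chrom != config.causative[0]]
    n_shared = min(config.n_background_shared, len(bg_chrom_exons))
    shared_exons = (
        [bg_chrom_exons[int(i)] for i in
         np.sort(rng.choice(len(bg_chrom_exons), size=n_shared, replace=False))]
        if n_shared else []
    )
    shared_keys = tuple(
        MutationKey(kind="deleted_exon", chrom=e.chrom, start=e.start, end=e.end,
                    exon_id=e.exon_id)
        for e in shared_exons
    )
    target_exons = [e for e in exons if e.chrom == config.causative[0]]
    cohort: list[MutantDataset] = []
    per_mutant: dict[str, tuple[str, int, int]] = {}
    for k in range(config.n_mutants):
        mid = f"m{k + 1:03d}"
        # distinct causative deletion: a unique run of exons for each mutant
        lo = (k * 7) % max(1, len(target_exons) - 3)
        own = target_exons[lo : lo + 3]
        per_mutant[mid] = (own[0].chrom, own[0].start - 1, own[-1].end + 1)
        keys = [
            MutationKey(kind="deleted_exon", chrom=e.chrom, start=e.start, end=e.end,
                        exon_id=e.exon_id)
            for e in own
        ]
        keys.extend(shared_keys)
        # a private SNP per mutant, unique coordinates
        keys.append(
            MutationKey(kind="snp", chrom=config.causative[0],
                        start=1000 + 17 * k, end=1000 + 17 * k, ref="A", alt="T")
        )
        cohort.append(MutantDataset(mutant_id=mid, mutations=keys))
    truth = TruthRecord(
        causative=config.causative,
        deletion=config.deletion,
        shared_background=shared_keys,
        per_mutant_deletions=per_mutant,
    )
    return cohort, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
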