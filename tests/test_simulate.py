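"""Simulator correctness: Mendelian limits, Haldane expectations, planted
deletion recovery, cohort construction, and determinism."""

import dataclasses

import numpy as np
import pytest

from bulkseg import background, exome, linkage, pipeline, simulate
from bulkseg.simulate import SimConfig


def test_marker_positions_sorted_in_bounds_with_mean_spacing(small_sim_config):
    markers = simulate.simulate_marker_positions(small_sim_config)
    for chrom, length in small_sim_config.chromosomes:
        pos = markers[chrom]
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 1 and pos.max() <= length
        mean_gap = np.diff(pos).mean()
        assert mean_gap == pytest.approx(small_sim_config.marker_spacing, rel=0.1)
    cchrom, cpos = small_sim_config.causative
    assert cpos in markers[cchrom]


def test_no_recombination_limit_gives_mendelian_genotypes():
    cfg = SimConfig(seed=3, chromosomes=(("chr1", 2_000_000),),
                    causative=("chr1", 1_000_000), deletion=None,
                    cm_per_mb=0.0, n_plants=3000)
    gen = simulate.simulate_f2_genotypes(cfg)
    dos = gen.dosage["chr1"]
    # no recombination: every plant's dosage is constant along the chromosome
    assert np.all(dos.min(axis=1) == dos.max(axis=1))
    freqs = np.array([(dos[:, 0] == k).mean() for k in (0, 1, 2)])
    se = np.sqrt(np.array([0.25 * 0.75, 0.5 * 0.5, 0.25 * 0.75]) / cfg.n_plants)
    assert np.all(np.abs(freqs - [0.25, 0.5, 0.25]) < 4 * se)


def test_mutant_pool_is_homozygous_reference_at_causative():
    cfg = SimConfig(seed=11, chromosomes=(("chr1", 5_000_000),),
                    causative=("chr1", 2_500_000), deletion=None, n_plants=300)
    gen = simulate.simulate_f2_genotypes(cfg)
    normal_pool, mutant_pool = simulate.select_pools(gen, cfg)
    dos = gen.causative_dosage()
    assert np.all(dos[mutant_pool] == 0)
    assert np.all(dos[normal_pool] > 0)


def test_too_small_population_raises():
    cfg = SimConfig(seed=1, chromosomes=(("chr1", 1_000_000),),
                    causative=("chr1", 500_000), deletion=None, n_plants=35)
    gen = simulate.simulate_f2_genotypes(cfg)
    with pytest.raises(ValueError, match="population"):
        simulate.select_pools(gen, cfg)


def test_mutant_pool_mo17_fraction_matches_haldane():
    """Among mutant-pool gametes, the Mo17-allele frequency at map distance d
    approaches the Haldane recombination fraction r(d)."""
    cfg = SimConfig(seed=29, chromosomes=(("chr1", 10_000_000),),
                    causative=("chr1", 1_000_000), deletion=None,
                    n_plants=8000, pool_size_mutant=1500, pool_size_normal=30)
    gen = simulate.simulate_f2_genotypes(cfg)
    _, mutant_pool = simulate.select_pools(gen, cfg)
    pos = gen.markers["chr1"]
    dos = gen.dosage["chr1"][mutant_pool]
    n_gametes = 2 * mutant_pool.size
    for target in (3_000_000, 6_000_000, 9_000_000):
        j = int(np.argmin(np.abs(pos - target)))
        d_cm = abs(int(pos[j]) - 1_000_000) / 1e6 * cfg.cm_per_mb
        r = 0.5 * (1 - np.exp(-2 * d_cm / 100))
        freq = dos[:, j].sum() / n_gametes
        se = np.sqrt(r * (1 - r) / n_gametes)
        assert abs(freq - r) < 3 * se + 1e-9


def test_pooled_reads_pure_mutant_at_causative_without_error():
    cfg = SimConfig(seed=17, chromosomes=(("chr1", 2_000_000),),
                    causative=("chr1", 1_000_000), deletion=None,
                    error_rate=0.0, n_plants=300)
    gen = simulate.simulate_f2_genotypes(cfg)
    calls = simulate.simulate_pooled_reads(gen, cfg)
    at = {c.pos: c for c in calls}[1_000_000]
    assert at.m_alt == 0


def test_normal_pool_fraction_converges_to_two_thirds():
    """1 AA : 2 Aa in the normal pool puts the Mo17 fraction at 2/3."""
    fracs = []
    for seed in range(12):
        cfg = SimConfig(seed=seed, chromosomes=(("chr1", 2_000_000),),
                        causative=("chr1", 1_000_000), deletion=None,
                        error_rate=0.0, depth_lambda=200.0, n_plants=300)
        gen = simulate.simulate_f2_genotypes(cfg)
        calls = simulate.simulate_pooled_reads(gen, cfg)
        at = {c.pos: c for c in calls}[1_000_000]
        fracs.append(at.n_alt / at.n_depth)
    mean = np.mean(fracs)
    # pool-composition variance dominates: sd(frac) ~ 0.043 at 30 plants
    assert abs(mean - 2 / 3) < 3 * 0.045 / np.sqrt(len(fracs))


def test_zero_depth_lambda_yields_unfilterable_sites():
    cfg = SimConfig(seed=2, chromosomes=(("chr1", 1_000_000),),
                    causative=("chr1", 500_000), deletion=None,
                    depth_lambda=0.0, n_plants=200)
    gen = simulate.simulate_f2_genotypes(cfg)
    calls = simulate.simulate_pooled_reads(gen, cfg)
    assert calls and all(c.n_depth == 0 and c.m_depth == 0 for c in calls)
    assert linkage.filter_biallelic_sites(calls) == []


def test_deletion_removes_markers_from_calls(small_sim_config):
    gen = simulate.simulate_f2_genotypes(small_sim_config)
    calls = simulate.simulate_pooled_reads(gen, small_sim_config)
    _, dl, dr = small_sim_config.deletion
    assert not any(dl < c.pos < dr for c in calls if c.chrom == "chr1")


# ---------------------------------------------------------------------------
# exome depths
# ---------------------------------------------------------------------------

def _single_gene_setup():
    """One explicit 39-exon gene (200 bp exons, 800 bp introns) plus a
    control gene on another chromosome; the deletion removes exons #13-#18
    and breaks inside the flanking introns (the intragenic single-gene
    case).  Returns (config, annotation)."""
    from bulkseg.types import ExonRecord

    g = 998_000
    exons = [
        ExonRecord("gchr1_0001", f"gchr1_0001.{j}", "chr1",
                   g + (j - 1) * 1000, g + (j - 1) * 1000 + 199)
        for j in range(1, 40)
    ]
    exons += [
        ExonRecord("gchr2_0001", f"gchr2_0001.{j}", "chr2",
                   50_000 + (j - 1) * 1000, 50_000 + (j - 1) * 1000 + 199)
        for j in range(1, 7)
    ]
    cfg = SimConfig(
        seed=23,
        chromosomes=(("chr1", 3_000_000), ("chr2", 3_000_000)),
        causative=("chr1", 1_012_000),
        deletion=("chr1", 1_009_500, 1_015_500),  # introns 12-13 and 18-19
        n_incidental_deletions=0,
    )
    return cfg, exons


def test_planted_six_exon_deletion_recovered_exactly():
    cfg, annotation = _single_gene_setup()
    control, mutant, exons, truth = simulate.simulate_exome_depths(cfg, annotation)
    deleted = pipeline.run_deletion_calling(control, mutant, exons)[0]
    expected = {f"gchr1_0001.{j}" for j in range(13, 19)}
    assert set(truth.deleted_exon_ids) == expected
    assert set(deleted) == expected
    eff = exome.cdna_deletion_effect(
        [e.length for e in exons if e.exon_id in expected]
    )
    assert eff["in_frame"] and eff["aa_removed"] == 400  # 6 x 200 / 3


def test_no_deletion_calls_nothing():
    cfg, annotation = _single_gene_setup()
    cfg = dataclasses.replace(cfg, deletion=None)
    control, mutant, exons, truth = simulate.simulate_exome_depths(cfg, annotation)
    assert truth.deleted_exon_ids == ()
    assert pipeline.run_deletion_calling(control, mutant, exons)[0] == []


def test_estimated_span_contains_planted_interval():
    cfg, annotation = _single_gene_setup()
    control, mutant, exons, truth = simulate.simulate_exome_depths(cfg, annotation)
    deleted_records = [e for e in exons if e.exon_id in truth.deleted_exon_ids]
    span = exome.estimate_deletion_span(mutant, deleted_records)
    _, dl, dr = cfg.deletion
    assert span.left_bp <= dl and span.right_bp >= dr
    # and the span is a superset of the deleted exons themselves
    assert span.left_bp < min(e.start for e in deleted_records)
    assert span.right_bp > max(e.end for e in deleted_records)


# ---------------------------------------------------------------------------
# cohorts and determinism
# ---------------------------------------------------------------------------

def test_cohort_shared_background_removed_exactly(small_sim_config):
    cfg = dataclasses.replace(small_sim_config, n_mutants=2, n_background_shared=5)
    cohort, truth = simulate.simulate_cohort(cfg)
    assert len(truth.shared_background) == 5
    res = background.filter_shared_mutations(cohort)
    assert {s.key for s in res.shared} == set(truth.shared_background)
    for m in cohort:
        assert set(res.unique[m.mutant_id]) == set(m.mutations) - set(truth.shared_background)


def test_single_mutant_cohort_loses_nothing(small_sim_config):
    cfg = dataclasses.replace(small_sim_config, n_mutants=1)
    cohort, _ = simulate.simulate_cohort(cfg)
    res = background.filter_shared_mutations(cohort)
    assert res.unique[cohort[0].mutant_id] == cohort[0].mutations


def test_same_seed_reproduces_identical_outputs(small_sim_config):
    a = simulate.simulate_dataset(small_sim_config)
    b = simulate.simulate_dataset(small_sim_config)
    assert a.calls == b.calls
    assert a.control_track == b.control_track
    assert a.mutant_track == b.mutant_track
    assert a.exons == b.exons
    assert a.gene_counts.counts == b.gene_counts.counts
    assert a.truth.deleted_exon_ids == b.truth.deleted_exon_ids
    c = simulate.simulate_dataset(simulate.with_seed(small_sim_config, 99))
    assert c.calls != a.calls


def test_dropout_genes_silenced_in_mutant_counts(small_sim_config):
    ds = simulate.simulate_dataset(small_sim_config)
    assert ds.truth.dropout_gene_ids
    for gene in ds.truth.dropout_gene_ids:
        n, m = ds.gene_counts.counts[gene]
        assert m == 0
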