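# bulkseg

Bulked-segregant linkage mapping combined with exome-capture deletion
calling, for finding the causative lesion in irradiation-induced mutants of
a sequenced inbred line (the motivating system is γ-irradiated B73 maize
kernel mutants outcrossed to Mo17).

## The problem and the method

A recessive mutant is crossed to a polymorphic mapper line and selfed; the
F2 segregates 3 normal : 1 mutant. Leaf RNA from ~30 plants per phenotype
class is pooled and sequenced, and variants are called jointly for the two
pools against the reference genome (reference allele = B73, alternate
allele = Mo17). Around the causative locus the mutant pool is homozygous
B73, while the normal pool (1 AA : 2 Aa) carries the Mo17 allele at an
expected fraction of 2/3.

**Positive sites.** A biallelic site (depth ≥ 5 in both pools, minor-allele
fraction > 20%) is *positive* when its Mo17-allele read fraction is ≥ 0.5
in the normal pool and the mutant pool shows the pure B73 allele (zero
alternate reads by default). Counting positive sites in 100-kb windows
stepped every 10 kb gives a genome-wide linkage profile: the window with
the maximal count marks the **linkage peak**; a run of ≥ 5 zero-count
windows inside or near the peak is a **linkage gap**, the footprint of a
deletion that removed every expressed marker locally. The simpler bulk
frequency ratio, BFR = (normal alt fraction)/(mutant alt fraction), is
provided as the noisier comparison statistic.

**Deleted exons.** From exome-capture depth tracks of the mutant and a
wild-type control, each annotated exon gets an accumulated depth
*D* = Σ per-base depth and a normalized depth 10⁹·*D*/(*L·D_a*), with *L*
the exon length and *D_a* the sample's total accumulated depth. An exon is
called deleted when the control normalized depth is > 30 while the mutant
raw depth is exactly 0. Consecutive deleted exons merge into one deletion
call; its breakpoints are the last/first covered positions flanking the
zero-coverage run, and the deleted length is `right − left − 1`.

**Background filter.** All mutants of one mutagenized population share the
stock's residual drift from the reference assembly, and identical induced
deletions in two mutants are essentially impossible: any mutation key
(deleted exon, SNP, or left-normalized indel) observed in ≥ 2 mutants is
discarded as background.

**Candidate ranking.** Deletions inside a linkage gap rank first, then
deletions inside the peak region, then expression-dropout genes (high
normal-pool, zero mutant-pool reads, fold change N/(M + 0.05)) inside the
peak, then deletions elsewhere; ties order by distance to the peak-window
midpoint. An empty top class yields an explicit "consider a regulatory or
intronic mutation" note.

A fully synthetic generator (Haldane-map F2 gametes, phenotype-bulked
pools, Poisson read depth with miscalls, capture-style depth tracks with a
planted deletion, dropout gene counts, multi-mutant cohorts) makes every
stage testable with no external data.

## Worked example

```pycon
>>> from bulkseg import deletion_length, cdna_deletion_effect, expression_fold_change
>>> deletion_length(176_913_222, 176_919_426)   # clone-sequenced breakpoints
6203
>>> cdna_deletion_effect([864 - 222])           # RT-PCR product difference
{'cdna_bp': 642, 'in_frame': True, 'aa_removed': 214}
>>> round(expression_fold_change(407, 381), 3)  # normal:mutant bulk counts
1.068
```

The 6203 bp between the two breakpoints span six exons; their 642 bp of
cDNA are a multiple of three, so the transcript stays in frame and the
protein loses 214 amino acids. A fold change near 1 says the deleted-exon
gene is still expressed from the remaining exons.

The same on a synthetic mutant end to end:

```pycon
>>> from bulkseg import simulate, pipeline
>>> cfg = simulate.SimConfig(seed=7)            # 10 x 50 Mb, pools of 30, 20x
>>> ds = simulate.simulate_dataset(cfg)
>>> scan = pipeline.run_linkage_scan(ds.calls, cfg.chrom_lengths)
>>> scan.n_positive
137
>>> scan.peak.peak_window
WindowCount(chrom='chr5', start=26830001, end=26930000, count=3)
>>> deleted, calls = pipeline.run_deletion_calling(
...     ds.control_track, ds.mutant_track, ds.exons, chrom_lengths=cfg.chrom_lengths)
>>> report = pipeline.run_candidate_integration(
...     "demo", scan, calls, ds.gene_counts, ds.gene_spans)
>>> report.candidates[0].evidence, report.candidates[0].deletion.length
('deletion_in_gap', 1000299)
```

The planted 1 Mb deletion (truth: chr5 between 24,500,000 and 25,500,001)
is recovered as the top-ranked candidate: the scan's widest gap
(chr5:24,370,001–25,460,000, 118 zero windows) overlaps it, and the
exome caller places its span at chr5:24,500,001–25,500,299.

A `bulkseg` command-line tool wraps the same steps:
`bulkseg simulate`, `bulkseg scan`, `bulkseg call-deletions`,
`bulkseg filter-shared`, `bulkseg integrate`, `bulkseg plot`.

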