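# Methods

## Scope and coordinates

`bulkseg` starts from pooled variant calls, exon annotation, per-base
depth tracks, and per-gene bulk counts; read trimming, alignment, pileup
and primary variant calling are upstream of the package. All internal
coordinates are 1-based inclusive; BED/bedGraph conversion happens only at
the I/O boundary. The reference allele is assumed to be the mutagenized
inbred's (B73) allele and the alternate the mapper line's (Mo17), because
reads are mapped to the inbred's own reference assembly.

## Positive-site classification

A site enters the scan when both pools have depth ≥ `min_depth` (5) and
the allele-fraction rule holds. The >20% minor-allele rule is applied, by
default, to the normal pool only (`scope="normal_bulk"`, with an
alt-fixed escape), because requiring both alleles above 20% in the mutant
pool would contradict the homozygosity requirement the classifier imposes
next; `pooled` and `each_bulk` scopes are available. Positivity then
requires the normal-pool Mo17 fraction ≥ 0.5 (inclusive: a pool of pure
hemizygotes sits exactly at 0.5) and the mutant-pool alternate fraction ≤
`mutant_homozygosity_tol` (0 by default — not one non-reference read; an
error-tolerant fraction can be configured).

## Window scan, peak, and gaps

Windows of 100 kb are anchored on a fixed 10-kb grid starting at
coordinate 1 (a fixed grid makes outputs reproducible; trailing windows
are truncated at the chromosome end and not length-normalized). The peak
window is the genome-wide maximal count. Because counts are small
integers at realistic marker densities, ties at the maximum are common;
they resolve by the largest summed count within ±500 kb on the same
chromosome, falling back to genome order. The 500-kb radius is several
window widths yet well below the linkage-decay scale (~1–2 cM): a larger
radius would let windows megabases away borrow the peak's own support,
and a plain genome-order rule systematically reports the leftmost of the
tied windows, which can sit megabases from the locus. The peak *region*
is the contiguous run of windows with count ≥ 25% of the maximum around
the peak window; gaps are maximal runs of ≥ 5 zero-count windows within
±3 Mb of the region, flanked on both sides by nonzero windows, reported
as the interval between the flanking windows. With overlapping windows a
zero-run of k windows has a nonempty interval only when
(k+1)·step > window; shorter runs are suppressed. The 25% region
threshold, 3 Mb flank, and 5-window minimum are package defaults exposed
in the API; no multiple-testing correction is applied anywhere, matching
the descriptive character of the scan.

## Exome deletion calling

`D_a` is taken literally as the sum of every per-base depth in the
sample's track; for capture data this equals the captured depth, since
uncovered positions contribute nothing. The "zero in the mutant" rule is
applied to the raw accumulated depth (integer 0), not the normalized
value, with `max_mutant_D` as an explicit tolerance; the control
threshold is a strict `norm > 30`. Deleted exons that are consecutive in
annotation order merge into one call unless the mutant track shows
coverage between them (retained sequence implies two deletions).
Breakpoints are reported as the last/first covered positions outside the
zero run, and the deleted length is `right − left − 1`; this convention
reproduces both printed-coordinate worked examples in the package tests
(6203 and 4804 bp), whereas an inclusive-span convention reproduces
neither. A side with no covered flank is reported at the chromosome bound
with a truncation flag. Positions the control itself never covers cannot
distinguish deletion from capture failure, which is why calls are
anchored only by exons passing the control-depth test.

## Background filter

Occurrence counts distinct mutants, never records: duplicates within one
mutant deduplicate first. Deleted exons are keyed by annotation identity
(the caller emits whole annotated exons); SNPs by upper-cased alleles and
position; small indels are left-normalized against reference context when
supplied (VCF-style: trim shared trailing bases, extending leftward with
the preceding reference base, then trim shared leading bases), otherwise
compared as given with a warning.

## Candidate ranking

Evidence classes, strongest first: deletion in a gap, deletion in the
peak region, expression dropout in the peak region, deletion elsewhere;
within a class, ascending distance from the peak-window midpoint to the
candidate's nearest edge (infinite across chromosomes), then label — a
total order, so reports are input-order invariant. Bulk counts are
normalized as counts per million (the minimal defensible choice; the
fold-change formula N/(M + 0.05) is scale-explicit, and the pseudocount
0.05 is applied on whatever scale the counts are supplied in). P-values
are not computed; an external differential-expression p-value column can
accompany the report but never reorders it.

## Synthetic data generator

The generator emulates the study conditions: 10 chromosomes of 50 Mb,
one biallelic marker per 50 kb on average, pools of 30 plants per
phenotype class (the study's pools held 21–30), mean pooled depth 20 per
site and pool, per-read miscall rate 0.002, a uniform 1 cM/Mb map, and a
1 Mb causative deletion centred on the causative locus. Markers are
placed one per 50-kb bin uniformly at random: inter-line SNPs never sit
on a lattice, and an exact lattice is also degenerate for the scan (every
100-kb window would hold exactly two markers, making all informative
windows tie). Recombination uses the Haldane map function without
interference; each plant is two independent gamete Markov chains.
Plants contribute equally to pool allele frequencies and reads are
binomial given the pool frequency, so the key expectations stay closed
form: normal-pool Mo17 fraction 2/3 and mutant-pool 0 at the causative
marker. Capture-style depth is Poisson per base over exons ± a 100 bp
flank and zero elsewhere; the mutant track is forced to zero inside the
deletion, one background exon is knocked out as a non-causative decoy,
and cohort simulations plant shared absent exons across all mutants for
the occurrence filter. One master seed drives labelled independent
sub-streams, so adding a stage never perturbs earlier ones. Phenotype
misclassification is available (default 0) for robustness studies.

What the generator does not emulate: uneven, gene-restricted marker
density; capture-efficiency and GC bias; alignment artifacts; DNA-amount
variation between pooled plants; crossover interference. Passing tests
therefore demonstrate correctness of the algorithms under an idealized
pool model, not performance on real tissue pools.

## Problem sizes and numerical choices

The Monte-Carlo acceptance battery runs 20 full pipeline replicates of
the default genome (~10,000 markers, ~1,100 exons each), which completes
in seconds; the Haldane-expectation check uses 8,000 plants on a single
10 Mb chromosome. Thresholds are compared strictly as documented
(`norm > 30` strict, normal fraction ≥ 0.5 inclusive, mutant tolerance
≤). Zero-depth sites are skipped with a log entry rather than raising.

## Known limitations

* **Peak resolution at sparse marker density.** At 20× pooled depth a
  mutant pool carrying one or two recombinant Mo17 gametes (pool
  frequency 1/60–1/30) still shows zero alternate reads roughly half the
  time, so positive sites extend several cM from the locus; with ~2
  markers per window, the genome-wide argmax window then lands more than
  2 Mb away in a substantial minority of replicates (the 20-seed battery
  typically localizes within 2 Mb in ~50–90% of replicates depending on
  the seed stream). Deeper sequencing or denser markers sharpen the peak;
  the downstream gap/deletion intersection and candidate ranking are
  robust to this, and the planted deletion is top-ranked essentially
  always.
* Deletions that remove no captured exon (regulatory or intronic lesions)
  are invisible to the depth caller by construction; the report's
  explicit note covers this outcome.
* The read-depth caller detects absence only; copy-number gains and
  split-read breakpoint refinement are out of scope.
* The occurrence filter assumes mutants are independent lines; related
  lines sharing a true causative deletion would filter it away.
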