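# Methods

## Overview

`proteocnv` analyses how chromosomal copy-number changes propagate to protein
levels in aneuploid cells measured against a diploid control. It has four
analysis stages — quantification/integration, genome profiling, 2D annotation
analysis, reporting — plus a synthetic-data generator that reproduces the
statistical structure the analysis assumes, so that every stage can be tested
quantitatively without access to raw mass-spectrometry or SNP-array data.

## Quantification and integration

Protein changes are SILAC ratio-of-ratios: each unlabeled sample is mixed
with a common heavy-labeled standard, and

    protein_log2 = log2( (tumor/standard) / (control/standard) )

cancels the standard. Records need at least `min_events = 2` quantification
events per experiment; replicate values are combined per gene by the median
(robust to one outlier replicate among three; an even count uses the mean of
the two middle values). Gene copy number is the median smooth signal of the
probes annotated to the gene, normalized to the same gene in the diploid
control (control values below 0.25 copies are floored to keep the log ratio
finite and the record is flagged). Proteins and genes are joined on gene
name; duplicate protein groups mapping to one gene keep the record with the
most quantification events, ties broken by smallest genomic position.
Protein log-ratios are median-centered genome-wide by default (`center`
switch), so "no change" sits at zero for the window tests.

A histogram-mode check on the control probe signal (expected mode ~2, warn
outside [1.8, 2.2]) guards the diploid-control assumption; a configured
chromosome (e.g. Y in female lines, where probes pile up at zero) can be
dropped before the check.

## Genome profiling

The profiler asks whether proteins that are *adjacent on a chromosome* are
coordinately up or down, which is the proteomic footprint of an
amplification or deletion even when single-gene changes are buried in noise.

1. **Scan.** On each chromosome the position-ordered log-ratios are scanned
   with windows of every size in the ladder `round(3·√2^k)`, deduplicated,
   capped at (and always including) the chromosome length, at stride one
   gene. Each window's mean is tested against zero with a two-sided
   one-sample t-test; windows with zero variance get p = 1 when the mean is
   zero and the smallest representable p otherwise.
2. **Null ensemble.** Ten "randomized genomes" are built by permuting the
   log-ratio values genome-wide while keeping the gene ordering, and
   scanned identically. Genome-wide (rather than per-chromosome)
   permutation preserves the global value distribution, including the heavy
   tails contributed by real aberrations, which makes the null for large
   windows appropriately harsh.
3. **Posterior error probabilities.** A small p-value means different
   things for a 3-gene window and a chromosome-sized one, so p-values are
   converted to PEPs per window-size stratum: 20 histogram bins in log10 p,
   pep(bin) = min(1, f_null/f_obs) with π0 = 1 (conservative), where f_null
   is the per-permutation mean count and f_obs the observed count. Both
   counts carry a half-count pseudo-observation — with 10 permutations a
   zero null count in a bin bounds the null rate rather than establishing
   it, and an unsmoothed ratio lets a sparse bin claim PEP exactly 0, which
   the monotonization then propagates to every smaller-p bin. Empty
   observed bins are interpolated from neighbors (flat extension at the
   ends); finally PEP is made non-increasing in −log10 p within each
   stratum.
4. **FDR threshold.** The significant set is the largest PEP cutoff t with
   estimated FDR = (mean permuted windows ≤ t)/(observed windows ≤ t) at or
   below 2%, computed on windows (not positions). The numerator uses the
   standard finite-permutation correction (k+1)/(B+1). `fdr = 0` yields an
   empty set by definition.
5. **Profile.** Each gene position takes the median of the intersecting
   significant window whose median deviates most from zero (ties go to the
   smaller window); positions intersected by no significant window are
   exactly zero. Copy-number estimates are `2·2^profile`. Maximal same-sign
   nonzero runs are exported as amp/del segments (BED, score =
   min(1000, |log2|·1000)).

### Boundary resolution — a known limitation

The profile is the union of all significant windows. A window one √2 step
larger than an aberrant segment that overhangs its ends still has a
near-full median and an extreme p-value, so the called region inherently
extends past the true boundary by a fraction of the segment length;
chromosome-scale windows containing a strong segment are also genuinely
non-null and paint the rest of the chromosome with a small median.
Measured on planted segments of 15–60 genes with shifts of 2–5 noise SDs,
*detection* (a same-sign call overlapping the segment at half amplitude) is
~99%, but boundary placement is off by a median of ~30 genes. The method
localizes aberrations to the region scale; it is not a breakpoint caller,
and segment ends should be refined with the copy-number data itself (or a
changepoint method) when exact boundaries matter.

`segment_recovery` therefore scores planted segments with an explicit,
documented rule: the recovered region is the maximal run of same-sign
positions with |profile| at or above half the planted amplitude, and
"recovered" additionally requires both boundaries within a configurable
tolerance (default 3 genes, rarely met for the reason above).

## Two-dimensional annotation analysis

Each annotation term (GO BP/MF/CC, KEGG, CORUM, plus one pseudo-term per
chromosome) splits the matched genes into members and complement. Per
dimension (copy log2, protein log2) the tie-corrected standardized
Mann-Whitney statistic z_d compares the two groups; the combined statistic
z₁² + z₂² is referred to χ² with 2 degrees of freedom. This realization is
rank-based, reduces to the ordinary Mann-Whitney in one dimension, and is
exact under independence of the dimensions at large n; correlation between
the dimensions inflates it, so an exact label-permutation p-value is
available (`method="permutation"`, default 10,000 draws). In the default
synthetic conditions the dimension correlation is ~0.25 and the measured
size of the analytic test is indistinguishable from nominal (null-term
p-values KS-uniform, empirical FDP ≈ 4–6% at BH 5%).

Terms are intersected with the matched universe first and kept when
`min_category_size ≤ m ≤ n − min_category_size` (default 5; rank statistics
are unstable below that). BH controls the FDR across terms at 5%. Per
dimension the difference score rescales the members' mean rank to [−1, 1]:

    score = (meanRank_members − (n+1)/2) / ((n−m)/2)

so 1 means all members are the largest values, 0 background-like, −1 all
smallest; rank-sum conservation makes the complement's score exactly the
negative.

## Synthetic data model

* **Genome.** Chromosomes are partitioned into segments with geometric
  lengths (mean 50 genes) carrying i.i.d. integer copy states weighted
  {1: 0.15, 2: 0.60, 3: 0.15, 4: 0.10} — an aneuploid genome with ~40% of
  genes at non-diploid copy, both focal and arm-scale events. Probes
  (5 per gene) report the state plus Gaussian noise (sd 0.2 signal units);
  the control reports 2 throughout. Copy state 0 is supported; its log2
  ratio is floored at −5 (residual protein; keeps t-tests finite).
* **Proteome.** Protein log2 means follow a linear dosage response,
  `alpha_g · log2(c_g/2)`, with `alpha_g = attenuation_alpha` (default
  0.25) for a dosage-sensitive fraction (default 1.0) and 0 otherwise,
  plus per-gene biological noise (sd 0.45) and small per-replicate
  technical noise (sd 0.1) on each ratio against the standard. These
  defaults put the raw copy-protein Pearson r at ~0.2–0.3 and the variance
  explained at a few percent — the dosage-dominated-by-other-regulation
  regime the analysis is designed for. A configurable fraction (5%) of
  records carries a single quantification event to exercise the filter.
* **Annotations.** Random terms of 10–60 genes, plus planted terms whose
  members receive a configured (copy, protein) log2 shift — by default one
  term shifted +1 in the proteome only, the signature of a regulated
  process independent of gene dosage.
* **Planted tracks.** For profiling experiments, `simulate_planted_track`
  writes regional shifts directly into a Gaussian protein track, and
  `place_random_segments` lays out non-overlapping, sign-balanced segments.

What the generator does **not** emulate: peptide-level evidence and missing
proteins, LOH/allele-specific signal, GC waves and probe-density variation
in the array signal, correlated biological regulation between neighboring
genes (beyond planted terms), and subclonal/fractional copy states. Passing
tests therefore demonstrate the statistical machinery under the stated
model, not performance on any particular real dataset.

## Numerical choices

* log2 throughout; profile→copies is then exactly `2·2^v` with integer
  copies at integer log2 values.
* Even-count medians are the mean of the two middle values (bit-stable).
* Zero-variance windows: p = 1 (mean 0) or smallest positive double.
* PEP histograms: 20 bins per stratum, π0 = 1, half-count pseudocounts,
  flat extension outside the observed range, running-minimum
  monotonization.
* FDR: permutation estimate with (k+1)/(B+1) numerator; window-level.
* Ranks: average ranks for ties, tie-corrected U variance.
* Degenerate correlations (<3 genes or zero variance) return NaN with a
  warning rather than raising.

## Problem sizes

Default experiments use 10 chromosomes × 300 genes (raw-vs-profiled
correlation), 5 × 300 with 6 planted segments × 20 seeds (recovery and null
calibration), 5,000 genes (variance-explained oracle), 10,000 disjoint
windows (t-test calibration), and 1,000 null terms × 50 seeds (annotation
FDP). These sizes give stable estimates while keeping a full run in the
low minutes on one core.
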