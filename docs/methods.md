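# Methods

## The subtraction estimator

A bisulfite-converted (BS) array probe reports methylated signal from both
5mC and 5hmC; oxidative bisulfite (oxBS) conversion oxidizes 5hmC to 5fC,
which reads as unmethylated, so the oxBS beta reports 5mC alone. With paired
conversions of the same DNA, the per-probe per-sample 5hmC estimate is the
difference of beta values, Δβ = β_BS − β_oxBS, and the three analysis
datasets are Δβ (5hmC), β_oxBS (5mC) and β_BS (total methylation). The
identity Δβ + 5mC = total holds exactly at every non-missing cell and is
asserted in tests.

Because both betas are noisy, Δβ can be negative. Negative values are
**retained** for all statistics: the FhmC caller uses a strict Δβ > 0.1
threshold (negatives can never qualify) and the rank-sum test operates on
raw values, where pre-clipping would distort ranks near zero. Clipping to 0
(`clip_nonnegative`) exists only for reporting and clustering outputs, where
a negative 5hmC level is not interpretable.

A side effect of the shared oxBS term is a built-in negative correlation
between the 5hmC and 5mC datasets' noise: a sample whose oxBS beta is high
by chance is simultaneously pulled toward hyper-5mC and hypo-5hmC. False
calls in the two datasets are therefore not independent, which is worth
remembering when reading cross-tabulations of direction sets.

## Detection-p filtering

The filter is two-stage: samples accumulating at least `sample_fail_n`
probes with detection p > 0.01 are dropped first, then probes failing in at
least `probe_fail_n` of the *surviving* samples. Samples-first ordering was
chosen (the source procedure does not state one) because a single bad
hybridization should not condemn probes that behave well elsewhere. The
array-scale default `sample_fail_n = 5500` is meaningless on small matrices,
so values below 1 are read as a fraction of the probe count. A probe-level
failure is counted on the union of the BS and oxBS conversions' detection p
when both matrices are supplied. The filter is idempotent.

## FhmC calling

A probe is a frequently hydroxymethylated site when Δβ strictly exceeds
`level` (default 0.1) in at least `frac` (default 0.5) of its non-missing
samples — computed as `count/total >= frac` with no rounding, so with 17
samples the rule requires 9. Missing cells leave both numerator and
denominator, which avoids penalizing probes with sporadic detection
failures. Raising `level` or `frac` can only shrink the called set
(monotonicity, property-tested).

## Differential testing

Per probe, young and old groups are compared with a two-sided Wilcoxon
rank-sum test. With pooled n ≤ 20 and no ties the p value comes from exact
enumeration of the rank-sum null (the 11-vs-6 design always qualifies);
otherwise the tie-corrected normal approximation without continuity
correction is used, and a completely tied probe gets p = 1. The exact path
is validated against full permutation enumeration for all group sizes ≤ 6.

Multiplicity control follows the source procedure literally: only p values
below `p_gate = 0.05` enter Benjamini-Hochberg adjustment, with m equal to
the size of that subset, and `passed_fdr` means q < 0.25. Note that this
gated adjustment is essentially vacuous as an FDR control: the largest
gated p is below 0.05, hence every gated q ≤ 0.05 < 0.25, and the gate
itself (raw p < 0.05) is what limits calls. The conventional all-probe
adjustment is available as `adjust_all=True` and is what the validation
suite uses when it measures false-discovery behavior; the default remains
the literal procedure so that published-style outputs are reproduced.

The shift-size filter then removes the floor(0.30 · n) FDR-passing probes
with the smallest |mean(old) − mean(young)| ("average change", so means, not
medians), with |shift| ties broken by probe id for determinism. Because the
trimmed fraction (0.30) exceeds the FDR bound (0.25), the filter removes
essentially all false calls when effects are strong — at the cost of
trimming a few true ones: on synthetic spikes the detection stage recovers
100% and the final set has empirical FDR ≈ 0 with recall around 0.8–1.0
depending on the realization. Direction (hyper/hypo) is the sign of the
shift among finally significant probes.

## Genomic context

Probes are 1-based single-bp sites; all tracks are 0-based half-open (BED),
converted only at module boundaries. Region labels use the precedence
Promoter > 5UTR > 3UTR > FirstExon > Exon > Intron, default Intergenic. The
promoter is the 2 kb window upstream of the TSS, strand-aware, and outranks
transcript-internal labels from other genes — a probe upstream of gene A and
inside gene B is a Promoter. The ordering 3UTR > FirstExon is deliberate: it
follows the stated precedence list even though it may look surprising.
UTRs are the exonic portions outside the CDS (strand-aware); the first exon
is the transcription-order first block; implementation is interval-tree
based and is tested against an independent per-position brute-force labeler
on randomized annotations.

CGI status is assigned by distance to the **nearest** island: 0 → CGI,
≤ 2 kb → shore, ≤ 4 kb → shelf, else nonCGI; using the nearest island makes
the CGI > shore > shelf precedence automatic when flanks of adjacent islands
overlap. CpG density is the count of CG 2-mers in a 2 kb window centered on
the probe divided by floor(window/2) — the maximum number of
non-overlapping CG 2-mers; the overlapping-positions denominator
(window − 1) was rejected because CG cannot overlap itself. Windows
truncated at chromosome ends use the truncated length and are flagged. Gap
distances are bp to the nearest edge of the chromosome's centromere /
nearest telomere interval, 0 inside.

Track smoothing averages peak scores in fixed 100 kb bins with any-overlap
assignment (a peak spanning a bin boundary contributes its full score to
both bins; "found within" is ambiguous and this choice is symmetric); empty
bins are missing, not zero. Site enlargement turns point sites into
width-200 kb intervals clipped to chromosome bounds.

## Background-corrected enrichment

The array interrogates a biased sample of the genome, so all subset tests
use the array's own probes as the reference population. Qualitative
features build a contingency table over the background cross-classified by
subset membership: 2×2 per histone-peak or chromatin-state track (Fisher's
exact test, two-sided by the "probability no larger than observed"
definition), k×2 for region and CGI classes (Pearson chi-square without
continuity correction, plus per-category 2×2 follow-ups). BH adjustment is
applied within one analysis family — the features passed to a single
`enrich_qualitative` call (all cell-line × mark combinations together, all
cell-line × state combinations together); region/CGI/density/distance
analyses use raw α = 0.05, mirroring how such analyses are conventionally
reported. Effect size is the plain sample odds ratio ad/bc and its base-2
logarithm; a zero cell yields OR 0 or ∞ with log2OR missing (no Haldane
correction by default; `haldane=True` adds +0.5). Probe-in-feature
membership is point-in-interval containment of the probe coordinate.

Quantitative metrics (CpG density, gap distances) compare the subset
against the background *remainder* with the shared rank-sum implementation,
and report Cliff's Delta D = (#{x>y} − #{x<y})/(nm) ∈ [−1, 1], computed
from midranks in O((n+m) log(n+m)) and validated against the brute-force
double loop; a subset sitting below the background gives negative D. Under
uniformly drawn subsets the Fisher tests flag ~5% of features at p < 0.05
(measured 0.046–0.055 at background 10 000 / subset 1000).

## Synthetic cohorts

The generator emulates the study design: 11 young (ages 2–29) and 6 old
(63–89) donors, paired BS/oxBS betas per biological sample, a toy genome
with per-chromosome telomere and centromere gaps, CG-rich planted islands,
stranded multi-exon transcripts with CDS, histone-peak tracks per cell line
× mark, and chromatin-state tilings per cell line. Probe positions are
uniform over non-gap sequence so gap-distance statistics are non-degenerate.

5hmC is additive by construction: the BS mean is 5mC + 5hmC and the oxBS
mean is 5mC, so the subtraction estimator is unbiased for the planted
level. A fraction `frac_fhmc` (default 0.05) of probes carries 5hmC at
`fhmc_level` (default 0.2, comfortably above the 0.1 calling threshold) in
both groups. Differential spikes shift the old group by `effect_size`
(default 0.2): hyper-5hmC spikes add 5hmC at otherwise 5hmC-free probes,
hypo-5hmC spikes (drawn inside the FhmC set, so there is 5hmC to lose)
subtract it with a floor at 0, and 5mC spikes shift the oxBS level; the four
spike sets are disjoint. Base 5mC levels are bimodal (Beta mixture) as on
real arrays, bounded away from 1 wherever planted 5hmC plus an effect must
fit without clipping the mean.

Noise: each beta is drawn from a Beta distribution with the target mean m
and precision ν = m(1−m)/σ² − 1 mapped from `noise_sd` σ (default 0.03, a
plausible technical replicate scale; the study reports no within-group Δβ
variance, so this is a free parameter chosen once). This respects [0, 1]
without clipping artifacts; σ = 0 returns exact means, giving noiseless
limits for exact-recovery tests. All randomness flows from one seed through
separate annotation / beta / detection-p streams, so identical configs give
bit-identical outputs.

What the generator does **not** emulate: probe type I/II chemistry and IDAT
intensities, SNP-affected probes, batch effects, spatial correlation of
methylation along the genome, and any dependence of 5hmC on annotation
(tracks and spikes are placed independently). Passing tests therefore
demonstrate correctness of the estimators and calibration of the tests
under the design's sample sizes — not performance under real-array
artifacts, which the QC and batch-covariate passthrough only partially
address.

## Problem sizes used in validation

The test suite runs cohorts of 600–5000 probes and the acceptance script
2000-probe cohorts with 50 spikes at effect 0.3 and σ = 0.02, 200-repetition
type-I calibration at background 10 000, and 50 randomized toy annotations —
sizes at which every stage's behavior is already asymptotically stable for
the 11/6 design while the whole validation completes in well under a minute
per component.

## Known limitations

- The literal gated BH adjustment reproduces the published procedure but
  does not control FDR at 0.25 in the usual sense (see above); use
  `adjust_all=True` for orthodox control.
- With 6 samples in the old group the exact rank-sum test's smallest
  attainable two-sided p is 2/C(17,6) ≈ 1.6 × 10⁻⁴; single-probe evidence
  is bounded accordingly.
- Odds ratios from tables with zero cells are reported as 0/∞ rather than
  corrected; downstream consumers must handle missing log2OR.
- The pipeline accepts pre-normalized betas; within-array normalization and
  batch correction are upstream concerns (the sample sheet's batch column is
  carried through untouched).
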