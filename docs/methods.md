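# Methods

This note documents the models and procedures implemented in `methyldx`,
the defaults chosen where the underlying workflow leaves the construction
open, and what the synthetic-data tests do and do not demonstrate.

## Copy-number profiles from array intensities

### Signal model

A methylation array interrogates each CpG with a methylated (M) and an
unmethylated (U) channel. The combined intensity M + U at a probe is
proportional to the local DNA copy number times a probe-specific affinity.
Affinity cancels in the ratio against a reference panel of
copy-number-neutral samples, so the per-probe statistic is

    log2( scale · (M + U)_sample / ref_probe )

where `ref_probe` is the median (default; mean available) combined
intensity across ≥ 3 flat-genome reference samples, and `scale` matches the
sample's genome-wide median combined intensity to the reference median.
Median matching is the package's choice: the absolute brightness of an
array is arbitrary (scanner gain, input mass), and the median is robust to
the aberrant fraction of a tumor genome. Probes whose aggregated reference
falls below a configurable floor are excluded from all ratios.

### Binning

Probes are aggregated into genomic bins (default target 8000 genome-wide,
minimum 15 probes per bin; the bin value is the median member log2 ratio).
Bins are contiguous equal-probe runs within a chromosome; the genome-wide
target is apportioned to chromosomes by probe supply (largest-remainder
rounding) and is met exactly whenever the per-chromosome minimum-probe caps
do not bind. Equal-probe construction keeps per-bin sampling noise uniform,
at the cost of variable genomic bin width. Chromosome Y is excluded by
default; X is binned but treated separately in event calling (below).

### Baseline

The copy-number-neutral level is the shift *b* minimising the median
absolute deviation median(|log2ᵢ − b|) over all bins, found by grid search
over [min, max] of the bin values at 0.001 log2 resolution. The MAD
objective is piecewise linear and its minimiser set can be a flat plateau;
ties are broken toward the candidate nearest the profile median. This rule
is translation-equivariant — shifting every bin by +c shifts the baseline
by +c to within the grid step, leaving baseline-relative calls unchanged —
which an anchor at zero would not guarantee. On median-scaled profiles the
bulk of the genome sits near zero, so the two rules coincide in practice.
A MAD-minimising baseline assumes the neutral state occupies the largest
share of the genome; heavily aneuploid genomes can violate this (see
Limitations).

### Segmentation

Per chromosome, baselined bin values are segmented by recursive binary
splitting with a *circular* scan: the candidate is the interior run x[i:j]
maximising |mean(x[i:j]) − mean(rest)| / (σ̂·√(1/m + 1/(n−m))), with plain
prefix/suffix splits included as the i = 0 / j = n cases. The pair scan
matters for focal events: a 3–4-bin amplification inside a large segment is
found with both edges at once, where a single-split statistic would have to
isolate it in two underpowered steps. A candidate is accepted when a
permutation test (default 200 permutations, early-terminated once
significance is impossible) rejects homogeneity at α = 0.01; accepted cuts
are applied and the scan recurses. Minimum segment length is 2 bins.
Segment means are unweighted means of member bins, so they conserve the
binned signal exactly.

The permutation test bounds the achievable p-value by the number of
distinguishable arrangements: an event spanning k bins on a chromosome of n
bins cannot reach significance unless roughly k!·(n−k)!/n! < α. In
practice this means events narrower than ~3 bins at the configured
resolution are not reliably segmented — the reason the bundled test
fixtures use a 1600-bin scheme (≈ 1.9 Mb/bin on the down-scaled manifest)
for 8 Mb focal events.

### Event calling

Thresholds are baseline-relative. A segment with |mean| ≥ 0.4 and length
≤ 10 Mb is a focal amplification / homozygous deletion; any other segment
with |mean| ≥ 0.15 is a broad gain / loss (this includes focal
low-amplitude gains, which matter for the contamination scan). The 10 Mb
focal cap separating focal from arm-scale changes is this package's
default; the distinction is conventional rather than sharply defined.
Events overlapping one of the 29 bundled highlight genes (hg19 coordinates)
carry the gene symbol.

Sex chromosomes are skipped by event calling by default: the bundled
reference panel is all-female, so a male sample shows a genuine germline X
dosage shift (log2 ≈ −1 across the whole chromosome) that is not a somatic
event. With a sex-matched panel, X calling can be re-enabled
(`autosomes_only=False`).

### Purity

An integer somatic copy number n in a tumor of purity p is observed at

    log2( (p·n + (1−p)·2) / 2 )

(germline copy 2; on male sex chromosomes the germline term is 1). The
synthetic generator floors the dosage factor at 0.05, representing residual
signal (normal-cell contamination, background) under a homozygous deletion.
Decreasing purity strictly shrinks every amplitude toward zero, which is
why no universal log2 cutoff can decide whether a deviation is a real
chromosomal change; the 0.4/0.15 defaults assume purities ≳ 0.7, and
low-purity material needs case-level judgement.

## Cohort summaries

Per bin, the percentage of cohort samples whose baselined value is ≥ +t
(gain) or ≤ −t (loss), t = 0.15 by default — a deliberately permissive
threshold so that single-copy arm gains and high-level amplifications count
identically, which is the semantics of a frequency plot. Bins missing in a
sample drop out of that sample's denominator. Frequencies are invariant to
sample order and cohort duplication.

## Calibrated score interpretation

Scores are validated (every schema class present, each in [0, 1], sum 1
within 1e-6) and never renormalised — an unnormalised vector indicates an
upstream defect, and silently rescaling would change its meaning. The
family score is the exact sum of member class scores (the sum rule for
probabilities of disjoint events). The ladder applied to
max(best class, best family):

| range        | category                               |
|--------------|----------------------------------------|
| ≥ 0.90       | classifiable (class or family level)   |
| [0.84, 0.90) | borderline                             |
| [0.50, 0.84) | suggestive                             |
| < 0.50       | no match                               |

0.84 is the maximised-Youden-index operating point of the underlying
classifier and 0.9 the conservative default between it and the
maximum-specificity point (0.96); the borderline band is surfaced as its
own category rather than silently accepted, because its acceptance is
conditional on nothing else speaking against it. Within a classifiable
family the best member is reported as subclass when its own score reaches
0.5. When class and family both clear 0.9 the class-level result is
reported with the family attached as context. Control-class scores summing
to ≥ 0.3 raise a `control_elevated` flag (typical of low tumor content);
an explicit `low_purity` context annotates borderline/suggestive reports
that a lower score may be accepted as an indication of a specific
diagnosis. Reports list the scores above the 0.3 floor. The schema is an
editable YAML file so revised class sets load without code change.

## Quality control

- **Sex**: median combined intensity on X and Y relative to the autosomal
  median. Male: Y ratio ≥ 0.2 and X ratio ≤ 0.7; female: Y ratio < 0.2 and
  X ratio ≥ 0.8; anything else (or < 100 informative X probes) is
  undetermined. The thresholds are calibrated on the synthetic generator
  and exposed in configuration; germline sex dosage is not diluted by tumor
  purity, so calls are stable down to low purity. Mismatch with the
  reported sex flags a possible case mix-up.
- **Noise**: the median absolute difference of consecutive
  within-chromosome bin values. For i.i.d. Gaussian bin noise of sd σ the
  score is 0.6745·σ·√2; it is shift-invariant and robust to true
  copy-number steps because steps touch a sparse minority of bin junctions.
  Default grades: crisp < 0.1, unusable > 0.3 (forces a re-analysis
  recommendation). The metric is this package's definition — the routine
  workflow it models assesses noise by eye.
- **Contamination**: every sample with an amplification is checked against
  the rest of the batch for amplifications or focal gains at the identical
  region (reciprocal overlap ≥ 0.5; "identical" needs a tolerance once
  segment boundaries carry bin-level error). Only amplifications surface in
  a lightly contaminated recipient — a 5 % admixture turns a donor 20-fold
  amplification into a ≈ +1.0 focal gain, while a donor single-copy arm
  gain dilutes to ≈ +0.035, far below the 0.15 call threshold. Flags are
  advisory; contamination between amplification-free samples is
  undetectable by this route.
- **Consistency**: predicted top classes vs per-sample expectations; if
  every checked expectation fails, a batch-level warning suggests a
  systematic error such as a reversed plate order.

## MGMT

Both promoter probes' betas are clamped to [1e-6, 1−1e-6], transformed to
M-values log2(β/(1−β)), and fed to a logistic model p = σ(w₀ + w·m).
p below / above the configured band is unmethylated / methylated; inside
the band, not determinable. The band is exactly the preimage of
[cutoff_low, cutoff_high], and with non-negative weights the call is
monotone in each beta. No clinical coefficients ship with the package;
the model file must come from a clinically validated source for the array
platform in use.

## Synthetic data

The generator emulates: per-probe multiplicative log-normal affinity (drawn
once per manifest, shared by all samples so it cancels in ratios);
log-normal intensity noise (default sd 0.1 in log2 units — chosen to yield
the crisp-plot regime, bin-level noise ≈ 0.02–0.03 at the test binning);
integer copy-number segments diluted by purity; germline sex dosage;
per-channel convex mixtures for cross-contamination; extra multiplicative
dispersion for bisulfite-failure-like noise; and calibrated score vectors
with a controlled top class or family. Manifests use real hg19 chromosome
lengths: ~450,000 probes at full scale, ~30,000 at test scale so that a
full pipeline runs in well under a second.

It does **not** emulate: probe type I/II chemistry, dye bias, background
fluorescence, FFPE degradation profiles, subclonal heterogeneity (a truth
segment has one clonal copy number), GC waves, or correlated noise along
the genome. Passing tests therefore demonstrate the correctness of the
computations under a clean generative model, not robustness to every
artefact of real arrays; the noise and contamination checks probe the
failure modes the QC workflow is designed for, at amplitudes matching the
closed-form expectations.

Problem sizes used by the test and acceptance harnesses — 30k-probe
manifests, 800/1600-bin schemes, 5-sample panels, 50-genome recovery runs,
24-bin spiked events at purities 0.7–1.0 — are the package's test profile;
the defaults (8000 bins, 15 probes/bin) correspond to full array scale.

## Known limitations

- The baseline assumes a copy-number-neutral majority; near-haploid or
  heavily polyploid genomes can pull it to a non-neutral level.
- Allele-frequency information is not available from these arrays, so
  copy-neutral LOH and absolute copy numbers are out of reach; calls are
  relative dosage only.
- Events narrower than ~3 bins at the configured resolution are below the
  segmentation's permutation-test resolution.
- The contamination scan requires the donor to carry amplifications.
- IDAT ingestion is an adapter boundary only; intensities must be provided
  as tables produced by an external reader.
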