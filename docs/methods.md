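# Methods

This note documents the models, estimators and numerical choices behind
silkcnv: a read-depth copy-number-variation (CNV) discovery workflow for
silkworm-scale genomes, with a dual-caller consensus step, comparative
cross-sample analysis and comparative-Ct (qPCR) quantification, exercised
end-to-end on synthetic data with known truth.

## Depth model

The primary signal is the number of sequenced read starts per genomic bin.
For a diploid background the per-bin count is modelled as Poisson with mean
`lambda = w * coverage / read_length` (bin width `w` bp), scaled by
`copy_number / 2` inside a CNV and modulated multiplicatively by a smooth
function of bin GC content. All coordinates are 0-based half-open (BED
convention); 1-based coordinates appear only in human-readable output.

Assumptions: reads are mapped uniquely and independently (no mappability
structure), bias depends on GC only, and the background ploidy is 2
everywhere. Copy numbers are absolute integers in [0, 20].

## Bin-size selection

The bin width is the smallest multiple of 100 bp such that, at per-bin
two-sided significance `alpha` (default 0.01, `alpha/2` per tail) under the
Normal approximation `N(lambda, lambda)`:

* a 3-copy bin `~ N(1.5 lambda, 1.5 lambda)` exceeds the gain threshold
  `t_gain = lambda + z_{1-alpha/2} sqrt(lambda)`, and
* a 1-copy bin `~ N(0.5 lambda, 0.5 lambda)` falls below
  `t_loss = lambda - z_{1-alpha/2} sqrt(lambda)`,

each with probability at least `p_min` (default 0.95). The gain side binds
(`sqrt(lambda) >= 2 (z_{1-alpha/2} + z_{p_min} sqrt(1.5))`, i.e.
`lambda ~ 84` at the defaults), giving ~900 bp at 10x coverage with 100 bp
reads and 500–5000 bp across the 7.8–14.4x range of the four-silkworm
study — the kilobase scale that study reported. The construction is this
package's own; it is a detectability argument, not a reproduction of any
particular tool's internal rule.

## GC correction

A LOESS curve (degree 1, span 0.3 of the bins, 2 robustness iterations) of
raw count on GC is fitted over full, unmasked bins;
`corrected = raw * median(raw) / fit(GC)`. Properties enforced by tests:
the global median is preserved within 1%, correcting twice changes counts
by <1%, a genome with a single GC value is returned untouched (exact
identity), and bins where the fit is non-positive are masked. Bin GC is
always recomputed from the reference sequence; ambiguous (N) bases are
excluded from the GC denominator and bins that are >50% N are masked
(depth there is unreliable, as it is on unplaced scaffolds in real
assemblies). Terminal partial bins are kept but excluded from calibration.

## Segmentation (CBS)

Each scaffold's corrected counts are segmented by circular binary
segmentation. For a region of `n` bins the candidate changepoint pair
`(i, j)` maximises the pooled-variance two-sample t statistic between the
arc `[i, j)` and its complement on the circularised series:

    t(i, j) = (m_in - m_out) / (s_p sqrt(1/k + 1/(n-k)))

with `k = j - i` and `s_p` the pooled within-group SD. Ties are broken by
smallest `i`, then smallest `j`; an arc and its complement define the same
boundaries, so the split is well defined either way. A split is accepted
when a within-region permutation test of the max statistic gives
`p <= perm_alpha` (default 0.01, `n_perm = 1000`), then the procedure
recurses. The permutation loop stops early when the decision is settled:
once the exceedance count guarantees `p > perm_alpha` the split is
rejected, and with zero exceedances after at least 200 permutations
(running estimate `1/(1+m) <= perm_alpha`) it is accepted.

Raw CBS over-segments long scaffolds, so a final pass merges adjacent
segments whose means differ by less than one robust SD of the bin-level
noise (1.4826 x MAD of the residuals around segment means), smallest gap
first.

## Calling and the high-confidence filter

Segments with mean strictly above `t_gain` become gains, strictly below
`t_loss` losses (the thresholds of the bin-size rule, evaluated at the
sample's diploid level = median corrected count); everything else is
diploid. Absolute copy number is `round(2 * segment_mean / diploid_mean)`
(half away from zero), floored at 0 and capped at 20; adjacent same-state
calls merge with a bin-weighted mean. Strictness at thresholds and the
rounding rule are conventions fixed here so behaviour at boundaries is
reproducible.

The high-confidence filter keeps a call only if both gates pass:

1. `|mean_RD - genome_mean_RD| > k * genome_SD_RD` with `k = 3`;
2. a per-region chi-square test: `X^2 = (O - E)^2 / E` with `O` the
   observed total (corrected) count in the region and `E` the genome rate
   times the region size, 1 df, `p < 0.05`. The test is per region, not
   per bin, and no multiple-testing correction is applied — the filter is
   a stated decision rule, not an inference procedure.

**Background statistics.** `genome_mean_RD` and `genome_SD_RD` are computed
over *unique regions* — bins with less than half their span inside the
supplied segmental-duplication (SD) intervals. Both are robust: the centre
is the median, and the scale is `1.4826 * median|x_{i+1} - x_i| / sqrt(2)`
over successive unique-region bins within scaffolds. Copy-number segments
are locally constant, so genuine CNVs inflate neither estimate (only their
boundaries contribute outlying differences). A plain mean/SD would be
inflated by the very CNVs the filter is meant to judge — on synthetic
genomes with ~10% CNV content the plain robust SD overshoots the true bin
noise by ~40%, which would silently discard moderate (CN 1/3/4) calls.

## Ratio-based second caller and consensus

A second, independent caller mirrors tumour/control ratio pipelines. The
genome is cut into variable-width windows each containing `read_num = 150`
control read starts (the control is a user-designated sample or a simulated
diploid read set on the same reference); the per-window statistic is the
library-size-scaled sample/control count ratio, put on the copy-number
scale (x2). The series is denoised with exact 1-D total-variation
regression (direct taut-string algorithm), the fitted levels are rescaled
so the modal level maps to copy number `2 + ploidy_offset`, and snapped to
integers; runs of non-diploid windows become calls.

The smoothing strength parameter `lambda` (default 7) is mapped to the TV
penalty weight through the data's own noise level:
`weight = lambda * sigma_hat / 2` with
`sigma_hat = 1.4826 * median|successive differences| / sqrt(2)`. This
calibration makes the parameter meaningful across coverages and keeps the
limiting behaviour exact: noise-free series are returned untouched
(`sigma_hat = 0`), `lambda -> infinity` collapses to a single level, and
the number of fitted levels is monotone non-increasing in `lambda`. The
modal level is found as the peak of a quarter-copy histogram of fitted
values (refined to the mean within the peak bin) — a per-value mode would
latch onto long exactly-constant stretches such as homozygous-deletion
plateaus. `ploidy_offset` is exposed because the upstream tool's ploidy
adjustment is not re-derivable from its description; the default 0 treats
the modal level as diploid.

Consensus: a filtered read-depth call is retained when a same-state
ratio-caller call overlaps it by at least 1 bp (50% reciprocal overlap
available via an option). Retained calls keep the read-depth intervals —
bin-resolution boundaries are sharper than window-resolution ones — and
the dropped calls on both sides are reported.

## Comparative stage

Consensus calls from all samples are union-merged (>= 1 bp overlap;
abutting intervals stay separate) into copy-number-variable regions; each
(sample, region) cell holds the sample's absolute copy number (length-
weighted mode if several calls overlap the region), 2 where uncalled.
Sharing classes follow the carrier set: individual-specific (exactly one
sample differs from 2), group-specific (all of one group and no one else),
all-possessed (every sample), otherwise shared-other. "Shared" requires the
same direction of departure from diploid, not an identical copy number.

Samples are clustered by average-linkage (UPGMA) agglomeration on Euclidean
distances between integer copy-number rows. The agglomerator is written in
the package because the required determinism — on equal merge distances,
merge the pair whose smallest member name sorts first — is not guaranteed
by library implementations; library linkage serves as an independent
cross-check in the tests on tie-free data. Output is newick with branch
lengths equal to merge-height differences.

## SD overlap and gene content

A CNV "overlaps" an SD when they share >= 1 bp (configurable); SD intervals
are union-merged first so per-call overlap base pairs never exceed the call
length. Gene assignment is the same >= 1 bp rule against gene models (GFF3
1-based inclusive converted to 0-based half-open on load); an abutting gene
does not count.

## qPCR quantification

Comparative-Ct with amplification efficiency fixed at 2.0 (the `2^-ddCt`
formula assumes it; no efficiency correction is applied). Replicates are
averaged on the Ct scale, then `dCt = Ct_target - Ct_control`,
`ddCt = dCt_sample - dCt_reference`, `RQ = 2^-ddCt`, and estimated copies
`= RQ * reference_copies`. The F-test compares per-replicate copy-estimate
variances between a tested sample and the reference with
`(n-1, n-1)` df; both the two-sided p and the one-sided
"greater variance" p are reported, the one-sided one matching the
confirmatory decision rule (a real copy-number difference shows up as
excess variance across individuals at that locus).

**Replicates for validation.** Error propagation gives
`sd(ddCt) = 2 sigma / sqrt(r)` for Ct noise `sigma` and `r` replicates.
Rounding an 8-copy estimate to the nearest copy tolerates
`|ddCt error| < log2(8.5/8) ~ 0.087`, so at `sigma = 0.1` triplicates
(`sd ~ 0.115`) cannot do it reliably; the recovery benchmark therefore uses
`r = 12` (`sd ~ 0.058`), while the generator's default stays at the
field-standard triplicate.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design at desk scale: a multi-scaffold
reference (default benchmark: 10 scaffolds, ~5 Mb total) with a smooth
sinusoidal GC landscape spanning [0.3, 0.6] per kb window; SD annotations
covering ~1.4% of the genome; two "domesticated" and two "wild" individuals
with 20 CNVs each (copy numbers drawn loss-biased from {0, 1, 3, 4, 6},
lengths 10–35 kb) realised in four sharing classes; and single-end reads
(100 bp, MAPQ 60) Poisson-sampled per base pair at 5–15x with a sin-bump
GC-bias multiplier (default amplitude 0.3 centred at GC 0.45, renormalised
to mean 1). Constant-GC genomes use an evenly spread deterministic base
pattern so flat-GC identities are exact. Every stochastic operation takes
an explicit seed; identical seeds give byte-identical FASTA/SAM/BED output.

Deliberately absent: sequencing errors, SNPs/indels, paired-end structure,
mappability and repeat ambiguity, GC overdispersion beyond Poisson, SD
sequence homology (SDs are plain intervals), and library-specific artefacts.
Passing recovery benchmarks therefore demonstrates the correctness of the
algorithms under the stated model — Poisson depth proportional to copy
number with smooth GC bias — not their performance on real libraries,
where mapping ambiguity and overdispersion dominate the error budget.

## Validation problem sizes

The truth-based benchmarks run at: ~5 Mb / 4 samples / 10x for consensus
recovery (precision and recall at 50% reciprocal overlap); 4 x 300 kb with
one CNV per sharing class for the comparative stage; 10 Mb / 10x for GC
correction (10,000 bins); 100 random series of <= 12 bins for the
changepoint-vs-exhaustive-search check; 200 trials for comparative-Ct
recovery. These sizes give stable statistics while keeping a full
validation run around a minute on one core.

## Known limitations

* Absolute copy numbers are relative to the reference assembly; a collapsed
  repeat in the reference shows up as a gain in every sample.
* The chi-square gate treats corrected counts as Poisson counts; strong
  overdispersion in real data would make its p-values optimistic.
* The ratio caller's window boundaries quantise breakpoints to ~1.5 kb at
  10x; consensus inherits breakpoints from the read-depth caller instead.
* The bin-size rule is a Normal-approximation power argument; at very low
  coverage (lambda < ~30) the approximation thins and the selected width
  errs conservative.
* No multi-sample joint segmentation or normalisation: samples are called
  independently and only compared afterwards, as in the original design.
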