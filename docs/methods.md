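# Methods

This note documents the models, defaults and numerical choices behind
`oncocase`, and what the synthetic benchmarks do and do not establish
about behavior on real data.

## Variant model and somatic subtraction

Variant evidence is modelled at the allelic-fraction level: each record
carries per-sample alternate-read counts and depths, and the analysis
never touches reads. Coordinates are 1-based (VCF convention) for sites
and 0-based half-open (BED convention) for segments, with explicit
conversion (`pos - 1 ∈ [start, end)`) at every intersection.

**Filter cascade.** Three germline filters are applied in order:
population frequency (exclude when the population minor-allele frequency
is ≥ 1%, *strictly* — a variant at exactly 1% is excluded; a missing
frequency is treated as rare, since novel pathogenic variants must
survive), then the reference-range panel, then the reportable-range rule
(COSMIC membership OR membership of the ACMG secondary-findings panel).
Every variant lands in exactly one report bucket; the panels themselves
are user-supplied configuration, not part of the package.

**Subtraction.** Somatic = {tumor calls with AF ≥ `tumor_min_af` = 0.10}
minus {normal calls with AF ≥ `normal_min_af` = 0.05}, matched exactly on
(chrom, pos, ref, alt); multi-allelic records are decomposed to biallelic
on read so keys are unambiguous. Threshold comparisons are inclusive
("output at 5%" includes a variant at exactly 5%). Characterization
thresholds: homozygous at tumor AF ≥ 0.85; LOH-suggestive at tumor
AF ≥ 0.70 over a heterozygous normal genotype; "disruptive" =
{nonsense, frameshift, splice}. All are configurable; the defaults are
pragmatic clinical conventions, not estimated quantities. De novo status
is three-valued: a missing parental genotype yields *indeterminate*,
never *false*.

## Copy number and LOH

**Segmentation.** The binned log2 tumor/normal depth ratio is segmented
by recursive binary splitting: at each candidate split the two-sided
pooled-variance t statistic of the mean difference is computed from
cumulative sums; the best split is accepted when its statistic exceeds
`change_threshold` = 8 and both sides keep ≥ `min_bins` = 5 bins. A zero
pooled variance with unequal means counts as an infinite statistic
(noiseless step). The threshold is deliberately far above the null
maximum (≈ 3–4 for a few hundred Gaussian bins at sd 0.2) and far below
the statistic of a single-copy change (≈ 35 for |Δlog2| = 1 at 100 + 100
bins), so both the no-false-split and the exact-recovery regimes have
wide margins. Calls: loss ≤ −0.3, gain ≥ +0.3 log2 (a single-copy change
in a ~70%-pure tumor is ≈ ±0.4; the cutoff is relaxed for noise).

**LOH.** Informative hets are germline sites with normal AF in
[0.45, 0.55] (inclusive), quality ≥ 30 and depth ≥ 20 ("high quality" is
unquantified in clinical practice; these are conventional cutoffs). BAF
deviation is folded, |AF − 0.5|, since either allele may be lost. Runs of
consecutive deviating sites (≥ 0.15) are merged, bridging at most 2
consecutive quiet sites for robustness; bridged sites are not members, so
every member satisfies the deviation predicate and reported segment
bounds are member-site bounds. Runs with ≥ 10 members become segments and
inherit their class from the maximally overlapping depth-ratio call
(neutral → copy-neutral LOH, loss → deletion LOH, gain → allelic
imbalance with gain; absent depth evidence defaults to copy-neutral).
BAF evidence is not fed back into the depth segmentation: the two tracks
are detected independently and combined only at classification.

## Expression-outlier ranking

Normalization divides each sample by its median housekeeping FPKM and
log-transforms with a *relative* pseudocount:

    normalized = log2(FPKM / median_hk + ε) − log2(1 + ε),  ε = 0.1

Applying the pseudocount to the ratio (rather than to numerator and
denominator separately) keeps two properties exactly: a gene at the
housekeeping median maps to 0, and the report is invariant to a global
rescaling of a sample's FPKM — library-size effects cancel by
construction. At ε = 0 the formula is the plain log ratio.

Ranking inserts the test sample into the reference pool: per gene,
rank = 1 + (#reference strictly below) + ½(#ties), percentile =
rank/(n_ref + 1). The mid-rank convention makes ties *conservative*: a
gene at zero FPKM in the test and in many references sits near percentile
0.5 and is never flagged. Decile boundaries are inclusive (≥ 0.9,
≤ 0.1). Under an exchangeable continuous test sample the flagged
fraction is (⌊0.1(n+1)⌋ + n + 2 − ⌈0.9(n+1)⌉)/(n+1) → 0.20; zero-inflated
genes flag at roughly half that rate, which is why the null-calibration
benchmark uses an almost-fully-expressed compendium (continuous values)
rather than the default 50% expressed. Genes absent from the reference
after intersection are dropped, never imputed; genes with zero reference
variance are excluded from z scores.

## Mixture transform and tissue similarity

Raw counts are library-size normalized by median-of-ratios size factors
(per sample, the median over universally nonzero genes of the ratio to
the per-gene geometric mean). The expressed/non-expressed mixture is fit
per sample on log2(FPKM + 0.1): FPKM is heavy-tailed and its bimodality
appears on the log scale; fitting per sample (rather than pooled) lets
each library's depth and composition set its own threshold.

The EM uses one k-means(2) initialization (Lloyd on 1D values, quantile
start) plus 5 seeded random restarts to guard against label-swap optima;
convergence at relative log-likelihood change < 1e-8 or 500 iterations;
component sd floored at 1e-3. A solution with a component sd at the floor
is a degeneracy (typically a collapse onto the atom of exact-zero FPKM
values) and is discarded in favor of the best non-collapsed solution.
Components are ordered by mean. A fit is flagged *non-identifiable* when
a weight drops below 0.02 or the separation D = |μ₂ − μ₁| /
√((σ₁² + σ₂²)/2) is below 2 (effectively unimodal input); the transform
refuses unconverged fits. Internally all samples and restarts are run as
one batch of independent EM chains with per-chain convergence, which is
numerically identical to per-sample fitting but an order of magnitude
faster.

The likelihood transform maps each gene to the posterior probability of
the expressed component. It compresses variation among clearly expressed
genes toward 1 and among silent genes toward 0 while keeping the
expressed/non-expressed contrast — measured on simulations, variance
among truth-expressed genes shrinks while the standardized mean
difference between groups grows. Sample similarity is Pearson correlation
between transformed columns; the 2D view is t-SNE (scikit-learn,
`metric="precomputed"`, seeded) on distance = 1 − correlation, after
subsampling at most 100 samples per tissue type; assignment is a majority
vote among the k = 15 most-correlated reference samples, ties broken by
higher mean similarity among the tied labels' neighbors.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis relies
on, with seeds making every byte reproducible:

* **Variants** — depth ~ Poisson(`mean_depth` = 500; a deep clinical
  assay), alternate reads ~ Binomial(depth, true fraction). Germline hets
  at 0.5, homs at 1.0; somatic fractions uniform in [0.15, 0.5]; inside
  an LOH arm the tumor het fraction shifts to 0.85 (or 0.15; direction a
  per-segment fair coin), i.e. a ~70%-pure single-allele loss. Population
  AFs ~ Beta(0.2, 2) with 20% missing (novel); somatic events are novel.
* **Depth track** — per-bin segment log2 ratio plus Gaussian noise
  (sd 0.2 default); copy-neutral arms sit at 0, deletions at −1, gains
  at +0.58.
* **Expression** — two-component log-normal mixture (non-expressed mean
  0, expressed mean 5 on log2(FPKM+1), sd 1), gene on/off states shared
  within a tissue with 20% re-drawn per tissue so tissues are separable;
  housekeeping genes always expressed at a quarter of the component sd;
  outliers spiked at ±4 log2 (16-fold, a driver-scale effect). Down
  outliers are placed on universally expressed genes and up outliers on
  universally silent ones, so spiked signal is not confounded with
  ordinary tissue specificity.

Not emulated: sequencing error and mapping artifacts, GC/bin-length bias
in depth, subclonal heterogeneity and varying purity, batch effects
across compendium sources, gene–gene correlation, and count overdispersion
(the negative-binomial variance stabilization used on real count data is
out of scope; the log2 pseudocount transform stands upstream of the
mixture instead). Passing benchmarks therefore demonstrates correctness
of the *procedures* and their calibration under the stated noise models —
not robustness to every artifact of real sequencing data.

## Benchmark problem sizes

The standing benchmarks use: 5 × (500 germline + 20 somatic) variant
pairs for subtraction fidelity; 10,000 sites for the selection oracle;
10 × 2,000 hets over a 200 Mb three-chromosome genome with one
copy-neutral and one deletion arm for LOH recovery; 5,000 genes × 500
reference samples for null calibration; 2,000 genes × 200 references for
spike-in sensitivity; n = 2,000 two-component samples for mixture
recovery; and 10 compendia of 5 tissues × 50 samples × 2,000 genes for
tissue assignment. These sizes give each estimate a comfortable margin
over its tolerance while keeping a full run in tens of seconds.

## Known limitations

* The segmenter is a plain binary-segmentation procedure, not an HMM; it
  reports total-copy log-ratio classes only (no allele-specific integer
  copy number, no purity/ploidy estimation).
* LOH classification trusts the depth call it overlaps; discordant
  evidence (e.g. a BAF shift over a noisy neutral/loss boundary) resolves
  to the larger overlap.
* The outlier rank test assumes the reference compendium is an
  appropriate null for the test sample; tissue-restricted ranking is
  available (`tissue_subset`) but the default ranks against the whole
  compendium.
* t-SNE coordinates are reproducible for a fixed seed but not stable
  across seeds; only neighborhood structure (purity, votes) is treated as
  meaningful.
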