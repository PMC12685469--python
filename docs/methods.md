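# Methods

`oncoprofile` re-implements, as a desk-scale tested pipeline, the analysis
stack of an integrated tumor profiling assay: targeted-panel DNA sequencing
for copy-number variation (CNV) and absolute copy number (ACN), shallow
whole-genome sequencing (sWGS) for chromosome-level structural variants
(SVs) and a genome-instability readout feeding a composite homologous
recombination deficiency (HRD) call, RNA and DNA fusion evidence
integration, a transcriptome tissue-of-origin (TOO) classifier, and
longitudinal plasma ctDNA tumor-fraction monitoring with molecular-response
stratification. All stages operate on intermediate tabular representations
(coverage ratios, allele counts, bin counts, junction reads, count
matrices, amplicon reads), never on raw reads. A synthetic-data module
generates each of these tables with recorded ground truth, so every
estimator can be scored against known parameters.

## Coverage and admixture model

A tumor sample with tumor fraction `TF` and a region at total copy number
`c` has expected tumor/normal coverage ratio

    E[ratio] = (TF * c + 2 * (1 - TF)) / 2,

i.e. 1.0 for diploid. Inverting this gives the absolute copy number

    ACN = (2 * ratio - 2 * (1 - TF)) / TF,

clamped at 0 with a warning when noise drives the raw value negative.
Gene-level calls use fixed cutoffs on the raw segment-mean ratio:
amplification at ratio >= 2.0 (inclusive), loss strictly below 0.6.
Whether these cutoffs should be applied before or after TF correction is
ambiguous in the assay description; we apply them to the raw ratio, the
literal reading. Deletion zygosity is assigned from ACN at the midpoints
between integer copy states: homozygous at ACN <= 0.5, heterozygous at
0.5 < ACN <= 1.5. Samples below 20% estimated tumor content are flagged by
the QC gate (30% for HRD).

The segment mean is the **median** of per-probe ratios (robust to single
outlier probes, common in FFPE material); the arithmetic mean is available
by option.

## Tumor-fraction estimation from heterozygous SNPs

Full allele-specific copy-number fitters (FACETS-class) are out of scope;
only a TF is needed downstream. The estimator grids TF over (0.05, 1.0] in
steps of 0.005 and, for each candidate TF and each segment, picks the
integer copy state `(total, minor)` (totals 0-8) maximising the joint
likelihood of

* the segment ratio under a Gaussian around the admixture expectation
  (sd 0.05 by default), and
* the heterozygous-SNP alt counts under a *folded* binomial mixture: the
  alt allele sits on either haplotype with probability 1/2, so alt counts
  mix Binomial(d, p) and Binomial(d, 1-p) with
  `p = (minor*TF + (1-TF)) / (total*TF + 2(1-TF))`, clipped to
  [1e-3, 1-1e-3].

Segments are screened first with a likelihood-ratio test for allelic
imbalance (folded BAF vs 0.5; LRT cutoff 10); if no segment with at least
10 usable SNPs is imbalanced, TF is declared unidentifiable and must be
supplied by the caller. The reported interval is the 95% profile-likelihood
range. On simulated panels (30 probes and 50 SNPs per gene) truth TF in
{0.3, 0.5, 1.0} is recovered within 0.01 and true copy numbers within
~0.25 copies — consistent with the 0.1-0.4-copy deviation a high-density
panel achieves.

## Shallow-WGS structural variants

Bin counts are normalised to the genome median over non-sex chromosomes,
so the median autosomal ratio is exactly 1. The published event cutoffs —
loss below 0.5, gain above 1.3 — are stated as "log2 ratio" thresholds,
which is dimensionally inconsistent (every neutral bin, log2 ratio 0,
would sit below 0.5): we interpret them on the **linear** normalised ratio,
where they bracket the one-copy loss (0.5) and single-copy gain (1.5)
expectations of a pure tumor. A `threshold_space="log2"` switch preserves
the literal reading.

Detection is two-staged:

1. **Candidates** are maximal runs of >= 10 consecutive bins strictly on
   one side of neutral (`min_consecutive_bins`, default 10, suppresses
   single-bin noise).
2. **Classification** uses the run *median* ratio (runs can absorb a few
   neutral bins from an adjacent arm at their boundary; the median ignores
   them). A run is reported when its median departs from 1.0 by at least 5
   standard errors *and* reaches the loss/gain cutoff within a 2-standard-
   error tolerance. The per-bin noise scale is estimated robustly from
   first differences of adjacent bins (MAD / sqrt(2)), which is insensitive
   to the segment-level shifts themselves.

The threshold tolerance is essential, not cosmetic: a clean one-copy loss
in a pure tumor has expected ratio *exactly* 0.5, on the cutoff, so any
strict comparison of a noisy statistic against 0.5 misses it about half
the time, while the segment median pins it down to well under the
tolerance. With these defaults the caller shows zero false chromosome-level
events on 200 simulated flat genomes and detects every simulated full-arm
one-copy loss at TF = 1. The strict-threshold semantics of the cutoffs
themselves are preserved in the pure classification function
(`classify_bin_ratio`) used for boundary checks.

## Instability score and HRD

The genome-instability score of the original assay is defined in external
work we do not reproduce; `compute_wgi_proxy` is a **declared proxy**: the
number of called gain/loss segments spanning at least 10 Mb (scaled by the
genome's `scale`, so 10 kb on the 1/1000 toy genome) minus a calibration
offset (default 5 on the toy genome, so a flat genome scores strictly
negative). Only two things are assay-faithful and tested as such: a score
>= 0 (inclusive) means genomic instability, and the composite HRD call is
positive when the sample is unstable **and/or** carries a pathogenic
BRCA1/2 mutation, provided tumor content is >= 30% (otherwise
indeterminate). The evidence split (BRCA-only / instability-only / both) is
recorded for cohort summaries.

## Fusion calling and integration

RNA libraries are gated by QC: fail iff total reads <= 30 million (the
boundary fails), median insert < 100 bp, or coverage CV > 1. DV200 is
recorded for reporting but deliberately not a gate — the QC rule set omits
it. Calls on a QC-failed library are refused.

Thresholds: inter-gene RNA fusions are positive at >= 5 junction reads;
intra-gene exon-skipping events (gene5 == gene3, e.g. MET exon 14) at
strictly more than 10 reads — the assay's two stated conventions (">10"
prose vs ">=10" table) conflict, and the prose reading is the default.
DNA breakpoints are positive at >= 2 supporting reads, but only when the
breakpoint is covered by the panel design; uncovered events are
*not assessable*, never negative. Integration takes the union over
assessable sources with per-event provenance; when RNA failed QC the
result is DNA-only and flagged. The union construction makes the combined
sensitivity >= each single assay by design, which the tests verify on
random truth tables.

## Tissue-of-origin classification

Counts are normalised with TMM (trimmed mean of M-values): per-sample
factors against a reference library (the one whose 75th count percentile,
scaled by library size, is closest to the cohort mean), doubly trimmed —
30% of M-values and 5% of A-values on each side by rank — with inverse
asymptotic-binomial-variance weights, then rescaled to unit geometric mean.
FPKM uses effective library sizes (library size x TMM factor):
`counts * 1e9 / (length * libsize)`. Features are `log2(FPKM + 1)`,
standardised.

Gene selection uses a Gini score with threshold 0.3 (inclusive): the best
single-expression-threshold split scored as relative Gini-impurity
decrease, evaluated **one-vs-rest per class** and maximised over classes.
The one-vs-rest reduction matters: the raw multi-class relative decrease
of a perfect one-class separator is only `1/(k-1)` (0.25 for five
balanced classes, ~0.03 for 32), so no gene could clear 0.3 under the
naive definition. The score lies in [0, 1], is 1 for a gene that cleanly
isolates any one class, 0 for a constant gene, and depends only on the
sample ordering, hence is invariant to monotone normalisation changes. If
nothing clears the threshold the selector falls back to the top-k by score
with a warning.

The classifier is a single L2-regularised multinomial logistic regression
(seeded, calibrated probabilities) standing in for an AutoML ensemble
whose winning families were linear anyway; the model family is
configurable in principle and a stratified 10-fold cross-validation helper
is provided. Predictions report the top two labels with probabilities —
the convention for cancer-of-unknown-primary reporting. Accuracy is the
fraction of samples whose true label matches top-1 (top-2: either
reported label).

## Plasma ctDNA monitoring

Mutation positivity at ultra-deep amplicon depth uses a one-sided binomial
tail against the per-read background error rate: positive iff
`P(X >= alt | depth, error) < 1e-3` and alt >= 3. No plasma VAF cutoff is
printed by the assay; this rule is chosen so that 0.01% TF is detectable
at 100,000x with a 5e-5 background, matching the assay's combined-feature
limit of detection.

Tumor fraction per draw follows a strict three-tier hierarchy, with the
tier recorded: (1) mean VAF over positive mutations; (2) otherwise the
ichorCNA-style copy-number scalar when positive; (3) otherwise a linear
regression converting the fragment-length signal to TF (ordinary least
squares on calibration pairs, >= 3 points, non-constant signal), clamped
at 0 and floored at twice the model's residual SD so that predictions
inside the model's own noise do not create spurious positives. ctDNA
status is positive iff the hierarchical TF is > 0.

The tracked-mutation VAF convention is operational: expected VAF = TF
(`vaf_equals_tf=True` in the generator); the heterozygous-mutation
convention VAF = TF/2 is available by switch. The generator tracks 8
mutations by default (the assay designs 5-8 personalised assays and
selects the top 4-10 mutations; 4-10 are accepted).

LOD: the dilution design is a 0.5% TF sample diluted to 0.1%, 0.05%,
0.025% and 0.01%, in triplicate. `compute_lod` fits a probit of detection
probability on log10(level) and inverts it at the confidence level
(default 0.90); when the fit is degenerate (e.g. everything detected) it
falls back to the lowest level with empirical hit rate >= confidence, and
with no detections anywhere the LOD is declared above the tested range.
Under the documented error model the combined detector reaches >= 90% hit
rate at 0.01% TF, so LOD90 lands at the lowest tested level.

Molecular response: percent change is computed on the hierarchical TF;
responders show a decrease *strictly* greater than 50% (an exact 50%
decrease — left unassigned by the two phrasings ">50% decrease" and
"<50% decrease" — is classified non-responder). A ctDNA-negative baseline
is not classifiable. Survival analysis uses the Kaplan-Meier product-limit
estimator and Cox proportional hazards with Efron tie handling (lifelines),
plus a two-sided log-rank test.

## Synthetic data: what it emulates and what it does not

The default genome is a 1/1000-scale hg38 (22 autosomes + X/Y, 2 kb bins,
~1,550 bins, a 12-gene panel with 30 probes and 50 heterozygous SNPs per
gene), chosen so that full-genome Monte-Carlo loops run in milliseconds.
Noise models: multiplicative gamma probe noise (CV 0.08), gamma-scaled
Poisson (negative binomial, dispersion 0.02) for bin and amplicon counts,
log-normal expression (per-gene log2 means uniform on [3, 9], sd 0.7)
with Poisson count sampling, Gaussian noise on the plasma copy-number
(sd 0.005, reported only above an ichorCNA-like 3% detection limit) and
fragment-length (slope 2, intercept 0.01, sd 0.002) scalars. The
expression generator ships a Bayes-rule oracle that classifies samples
under the true generative model — the ceiling no trained classifier can
beat — used to verify that reported accuracies reflect genuine
separability.

Not emulated: read-level artifacts (GC bias, mappability, FFPE
deamination), probe-to-probe correlation, inter-gene expression
correlation and batch structure, clonal heterogeneity and subclonal copy
states, and real error-rate heterogeneity across amplicons. Passing tests
therefore demonstrate correctness of the estimators under their stated
models, not performance on real sequencing data.

## Problem sizes and numerical choices

Test and acceptance runs use: 3 tumor fractions x 12-gene panels for
recovery; 200 flat genomes (specificity) and 100 arm-loss replicates
(sensitivity) for the SV caller; 100 random fusion truth tables; a
5-class, 50-samples-per-class, 200-gene cohort (40 informative genes,
log2 fold change 4) split 50/50 for TOO; 500 plasma replicates per
dilution level for hit-rate monotonicity; and 100 two-arm exponential
simulations (200 per arm, true hazard ratio 4) for Cox interval coverage.
Ties in expression are never split (splits only between distinct values);
the TF grid excludes 0 by construction; probabilities in folded-binomial
likelihoods are clipped to avoid infinities at pure-tumor loss of
heterozygosity; all generators and fitted models are seed-deterministic.

## Known limitations

* The instability proxy is calibrated only on the toy genome; its offset
  has no meaning for real data.
* TMM factors are only approximately invariant to rescaling one library
  (the precision weights are depth-dependent); agreement is to ~1% rather
  than machine precision.
* The TF estimator assumes one dominant clone and integer copy states up
  to 8; it is not a substitute for full allele-specific segmentation.
* The fragment-length tier is a straight-line calibration; real
  fragmentomics signals saturate and would need a monotone nonlinear link.
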