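# Methods

This note documents the models implemented in `hmcseq`, the assumptions of
the synthetic-data generator that stands in for restricted-access cohorts,
and the numerical choices made where the procedure was genuinely open.

## Gene-body quantification

Fragments are counted over the *entire gene body* (genomic span, gene start
to gene end — not exonic length), with ≥ 1 bp intersection on the 0-based
half-open convention, and **multioverlap**: a fragment intersecting k gene
bodies increments all k counts. This matches featureCounts-style counting of
enrichment data, where reads cannot be attributed uniquely among overlapping
genes. Counts are normalized to transcripts per million:
`rate_g = counts_g / (length_g/1000)`, `TPM_g = 1e6 · rate_g / Σ rate`, so
every sample column sums to 1e6 exactly.

Promoters are `[TSS−2000, TSS+500)` on the plus strand and the strand
mirror `[TSS−500, TSS+2000)` on the minus strand (TSS taken strand-aware),
clamped at coordinate 0. Promoter methylation is the unweighted mean of CpG
methylation fractions inside the window (missing when the window holds no
CpG); gene copy number is the segment-length-weighted mean over the gene
body (missing when uncovered). Peak annotation assigns each peak one
category by its midpoint under the fixed precedence
promoter > exon > intron > downstream > intergenic; "downstream" is the
3 kb strand-aware window past the gene end. Midpoint plus an explicit
precedence order was chosen because it is deterministic and testable; the
width of the downstream window is a package choice.

All coordinates are stored 0-based half-open internally; 1-based inclusive
dialects are converted at the reader boundary.

## Integrative expression model

Per gene, OLS of z-scored log2(TPM+1) expression on z-scored log2(TPM+1)
5hmC, promoter methylation, copy number and SNV/SV counts. Z-scores are
computed cohort-wise per gene (the scaling population is a package choice;
it makes 5hmC coefficients comparable across genes). Missing values are
dropped listwise. Predictors that are constant in the remaining samples
(typically SNV/SV columns — most genes carry no variant in a cohort) carry
no information and are dropped from that gene's design; any residual rank
deficiency flags the whole fit missing rather than silently dropping terms.
Fits with fewer than p + 2 complete samples are missing.

The 5hmC contribution is reported two ways: ΔR²_adj between the full model
and the nested refit without the 5hmC term (all other coefficients refit),
and the partial F-test p-value of that comparison — identical to the
two-sided t-test on the 5hmC coefficient for a single added regressor, an
identity asserted numerically in the tests. Benjamini–Hochberg is applied
across all tested genes. Note that ΔR²_adj can be negative (the adjustment
penalty), while unadjusted R² is monotone in the predictor set; both are
asserted accordingly.

## Pre-ranked enrichment

The enrichment score is the weighted Kolmogorov–Smirnov running sum with
weight exponent 1 (hit increments ∝ |stat|, miss decrements 1/(N−m)); the
exponent is configurable, with exponent 0 giving the unweighted, rescaling-
invariant and antisymmetric statistic. The null permutes gene labels —
a deliberately simpler scheme than fgsea's adaptive multilevel sampler,
estimating the same quantity at desk scale. The p-value is the permutation
tail on the side matching the observed score's sign, with a +1 pseudocount;
this convention makes null p-values uniform, which the suite verifies by
Kolmogorov–Smirnov over 200 random sets. NES divides ES by the mean |null
ES| of matching sign. Sets overlapping the ranking in fewer than 3 genes
are skipped.

## Tissue deconvolution and the GI score

Reference-based scoring decomposes a profile over gene × tissue reference
columns by nonnegative least squares after per-gene standardization against
the panel, normalizing weights to the simplex. Standardization is linear
per gene, so simplex mixtures of panel columns are preserved and recovered
exactly in the noise-free case (to solver tolerance); this exactness is the
reason the optional log2(x+1) pre-transform — useful when profile and panel
arrive on raw TPM scale — is off by default. Row-centering makes the
standardized columns sum to the zero vector, leaving the simplex direction
unidentified from the data alone; a sum-to-one row is appended to the
design, which a true mixture satisfies exactly. Collinear (duplicate)
tissues trigger a warning and a pseudo-inverse fallback.

The GI score is the summed weight of colon, gastric, liver and pancreatic
tissue; samples are flagged GI-positive at score ≥ 0.25 (boundary
inclusive). Whether the original tissue-map scores sum to one is unknown;
the simplex convention is asserted only for this implementation.

## ctDNA fraction

Somatic variants must pass, conjunctively: ≥ 10 unique supporting reads;
VAF ≥ 1%; mean mapping quality ≥ 10 (base substitutions only, as indels are
not subject to the same alignment-quality failure mode); VAF ≥ 20× the
same-position background error; VAF ≥ 3× the paired germline allele
fraction; ≥ 20× leukocyte depth. Manual-curation outcomes are represented
as optional boolean columns honored when present. Germline calls require
≥ 8 reads, VAF ≥ 10%, population frequency < 0.5%, and a deleterious
consequence (frameshift, splice site, stopgain).

The surrogate variant is the maximum-VAF passing variant excluding
amplified genes (copy log-ratio > 0.2) and allosomes, with ties broken by
(chrom, pos). Under conservatively assumed loss of heterozygosity the
mutant allele is the only tumor copy, so VAF = t/(2−t) and
`ct = 2/(1 + VAF⁻¹)` — zero at VAF 0, strictly increasing, 1 at VAF 1. For
samples with copy-number evidence but no passing somatic variant, the
heterozygous-SNP major allele frequency in one-copy-loss genes satisfies
f = 1/(2−t), inverted as `t = 2 − 1/f` (clipped to [0,1]); this inversion
is a model-consistent reconstruction validated by binomial read simulation
rather than a published formula.

## cfDNA classifiers

Gene selection keeps genes whose log2(TPM+1) 5hmC correlates with tissue
tumor cell content at P ≤ 0.05 **and** Bonferroni-adjusted
q = min(1, p·G) ≤ 1e-5. Pearson is the default (the downstream model is
linear); Spearman is available by flag. The ct model is elastic-net linear
regression with the mixing parameter chosen from {0.1, 0.5, 0.9} by 5-fold
cross-validated MSE over the automatic lambda path, deterministic given the
seed; predictions are clipped to [0, 1] and genes absent from a profile are
imputed at their training means (more than 20% missing is an error).

Driver events use linear-interpolation quartiles across samples with
inclusive boundaries (≥ Q3 gain for AR/MYC/NCOA2, ≤ Q1 loss for
RB1/PTEN/TP53/BRCA2/NKX3-1), summed 0–8 and binned 0–1 / 2–3 / >3; the
TOP2A/EZH2 class counts top-quartile memberships (none/either/both). The
estimator and the inclusive tie rule are package choices; quartile flags
are invariant under strictly monotone per-gene transforms, but boundaries
are cohort-conditional — adding samples can move them.

## Survival

Tertiles split at the 1/3 and 2/3 linear-interpolation quantiles with
boundary values assigned to the lower group. Kaplan–Meier and Cox models
wrap lifelines; ties use the Efron approximation (lifelines' default), and
Wald tests/CIs come from the observed information. The per-event hazard
ratio enters the Cox model linearly, unadjusted and adjusted for
ct-fraction plus the clinical block (age at mCRPC diagnosis, PSA and Hb at
first-line ARSI, ARSI type as a binary indicator, prior docetaxel, time to
CRPC from ADT start, visceral metastases), all continuous covariates
untransformed.

## The synthetic generator

The generator emulates the study's data model, not its biology:

* **5hmC counts** are negative binomial (Gamma–Poisson,
  Var = μ + φμ²; φ = 0.3 by default) with mean ∝ gene length × per-sample
  library size factor. The real count distribution of enrichment
  sequencing is not established; negative binomial is this package's
  choice, and φ is a config knob.
* **Expression** is a linear combination of the z-scored log2(TPM+1) 5hmC
  signal, a Gaussian methylation latent (observed through a Beta(2,2)
  marginal, so the planted anticorrelation is monotone but not linear in
  the observed fractions), standardized copy number, and z-scored sparse
  SNV/SV indicators, plus Gaussian noise on the log2 scale. Because all
  generative predictors are standardized and independent, the population
  partial R² of the 5hmC term is β₅ₕₘC² / (Σβ² + σ²) — the closed form the
  recovery tests compare against.
* **Defaults** are the study conditions used throughout:
  93 samples (the tissue cohort size), 1000 genes at desk scale, half the
  genes 5hmC-coupled at β = 0.6, a universal copy-number dosage effect
  β = 0.3, methylation anticorrelation β = −0.3 for 30% of genes, noise
  σ = 0.8. These give per-gene 5hmC–expression correlations around 0.5 for
  coupled genes and realistic model R² in the 0.2–0.4 range.
* **cfDNA mixtures** are `panel · weights + Gaussian noise`, truncated at
  zero; **variant reads** are binomial at the copy-model VAF plus
  background error, with amplified-gene and allosome decoys that surrogate
  selection must reject; **survival** is exponential proportional hazards
  with planted log-hazards and uniform administrative censoring over 72
  months.

What the generator does *not* emulate: fragment-length biology of cfDNA,
peak-level structure (inputs are gene-level), spatially correlated copy
number, linked methylation blocks, or non-proportional hazards. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to every failure mode of real sequencing data.

## Problem sizes and numerical notes

The test suite and the acceptance script run the integrative model at
1000 genes × 93 samples, enrichment nulls at 1000 permutations (200 random
sets for calibration), tissue recovery over 100 Dirichlet mixtures,
ct-fraction round trips at depth 2000 × 50 variants across tumor fractions
0.1–0.9, and Cox recovery over 100 replicates of n = 300 — sizes chosen so
each stage's Monte-Carlo error is well inside its assertion band on a
single CPU. Variance uses the n−1 denominator throughout; variance-ranking
ties break lexicographically by gene id; zero-variance genes are excluded
from ranking and scaled to missing; NNLS runs at scipy's default tolerance
(recovery asserted to 1e-6); elastic-net iteration cap is 5×10⁴.

## Known limitations

* The tissue-scoring algorithm is a stand-in with the published method's
  input/output contract, validated against planted mixtures only — not
  against published tissue-map scores.
* Headline cohort statistics (median correlations, ΔR², significant-gene
  counts) depend on the planted generator conditions and are not estimates
  of the real cohort's values.
* The het-loss inversion assumes a single clonal one-copy loss; subclonal
  loss biases t downward.
* `fit_all_genes` loops genes through statsmodels OLS; at ~3 ms/gene this
  is comfortable at 10⁴ genes but not optimized for 10⁵-feature use.
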