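# hmcseq

Analysis toolkit for gene-body **5-hydroxymethylcytosine (5hmC)** enrichment
sequencing in prostate cancer tissue and cell-free DNA (cfDNA).

5hmC is an oxidized form of 5-methylcytosine that accumulates in the gene
bodies of actively transcribed genes, making it a DNA-based readout of
transcriptional activation. In metastatic castration-resistant prostate
cancer (mCRPC) this enables three kinds of analysis that `hmcseq`
implements end to end:

1. **Integrative expression modeling.** Per gene *g*, expression is modeled
   as

   `z(log2(TPM_expr + 1)) ~ z(log2(TPM_5hmC + 1)) + PM + CN + SNV + SV`

   by ordinary least squares, where PM is mean promoter CpG methylation
   (window −2000/+500 bp around the strand-aware TSS), CN the
   length-weighted gene copy number, and SNV/SV variant counts. The added
   explanatory value of 5hmC is ΔR²_adj between the full and the nested
   model without the 5hmC term; significance is the partial F-test with
   Benjamini–Hochberg control across genes.
2. **Lineage scoring of cfDNA.** A sample's 5hmC profile is decomposed over
   gene × tissue reference profiles by nonnegative least squares on the
   per-gene standardized scale; weights live on the simplex. The **GI
   score** (colon + gastric + liver + pancreatic weight) flags
   gastrointestinal lineage plasticity at ≥ 0.25.
3. **Liquid-biopsy tumor content and prognosis.** Somatic cfDNA variants
   pass read-support/error filters; the highest-VAF autosomal,
   non-amplified variant gives the circulating tumor fraction under assumed
   loss of heterozygosity, `ct = 2/(1 + VAF⁻¹)`, with a heterozygous-loss
   SNP fallback `t = 2 − 1/f`. An elastic-net model predicts ct-fraction
   from gene-body 5hmC directly; quartile-based driver-event scores (AR,
   MYC, NCOA2 gains; RB1, PTEN, TP53, BRCA2, NKX3-1 losses) and the
   TOP2A/EZH2 class feed Kaplan–Meier and Cox proportional-hazards models.

Because the motivating cohorts are access-controlled, the package ships a
first-class synthetic-cohort generator (`hmcseq.synth`) that plants known
effect sizes, tumor fractions, tissue mixtures and log-hazards, so every
stage is validated against ground truth.

## Worked example

```python
import numpy as np
from hmcseq import synth, integrate, lineage, variants

# a synthetic cohort: 500 genes x 93 samples with planted effects
cfg = synth.CohortConfig(n_genes=500, n_samples=93, seed=42)
genes, bundle, truth = synth.generate_cohort(cfg)

results = integrate.fit_all_genes(bundle)
s = results.summary()
print(s["median_adj_r2_with"], s["median_adj_r2_without"], s["n_significant"])
# 0.340  0.189  256

# cfDNA as a noisy tissue mixture; deconvolve and score GI lineage
panel = synth.generate_tissue_panel(seed=42)
w = np.array([0.55, 0.15, 0.10, 0.10, 0.05, 0.05])
profile = synth.generate_cfdna_mixture(panel, w, noise_sd=0.2, seed=7)
scores = lineage.tissue_scores(profile, panel)
print(round(lineage.gi_score(scores), 3))   # 0.311 -> GI-flagged (>= 0.25)

# ct-fraction from simulated targeted sequencing at true ct = 0.4
vt = synth.generate_variant_reads(true_ct=0.4, depth=2000, seed=3)
est = variants.estimate_ct(vt, sample_id="P1")
print(round(est.ct_fraction, 3), est.method)  # 0.425 vaf_formula
```

The integrative model recovers roughly half the genes as 5hmC-informative —
exactly the fraction the generator planted; the tissue scores recover the
mixing weights (prostate 0.544 for a true 0.55 at this noise level); and the
variant route inverts the read-level simulation back to the planted tumor
fraction.

A command-line interface mirrors the library:

```bash
hmcseq simulate --seed 1 --out cohort/
hmcseq integrate --cohort-dir cohort/ --out fits/
hmcseq tissuemap --profiles profiles.tsv --panel panel.tsv --out scores.tsv
hmcseq ctfraction --variants variants.tsv --out ct.tsv
```

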