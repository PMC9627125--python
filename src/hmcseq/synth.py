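"""Synthetic multi-omic cohorts and cfDNA mixtures with known ground truth.

The generator emulates the data model of a 5hmC enrichment-sequencing study
of metastatic prostate cancer at desk scale so every downstream stage can be
tested without restricted-access data:

* gene-body 5hmC counts drawn negative-binomial with gene-length-proportional
  means and per-sample library size factors;
* expression built as a linear combination of the z-scored log2(TPM+1) 5hmC
  signal, promoter methylation (Beta marginal, anticorrelated for a planted
  gene subset), copy-number dosage, and sparse SNV/SV indicators, plus
  Gaussian noise on the log2(TPM+1) scale;
* cfDNA profiles as reference-panel mixtures with known tumor fraction and
  tissue weights;
* sequencing-read allele counts at somatic variants under loss of
  heterozygosity (VAF = t / (2 - t) at tumor fraction t);
* survival times from an exponential proportional-hazards model with planted
  log-hazards and uniform administrative censoring.

Everything is deterministic given the seed; per-gene effect sizes, tumor
fractions, tissue weights and hazards are returned as :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import write_json, write_matrix
from .quantify import OmicsBundle, tpm_normalize

DEFAULT_TISSUES = ["prostate", "bone_marrow", "liver", "colon", "gastric",
                   "pancreatic"]


@dataclass
class CohortConfig:
    """Study conditions for :func:`generate_cohort`.

    Defaults emulate the tissue cohort: 93 samples, half the genes with a
    genuine 5hmC-expression coupling (effect 0.6 on the z-scale), a universal
    copy-number dosage effect (0.3), promoter methylation anticorrelated with
    expression for a gene subset (-0.3), and residual noise sd 0.8 on the
    log2(TPM+1) scale.
    """

    n_genes: int = 1000
    n_samples: int = 93
    frac_5hmc_coupled: float = 0.5
    frac_pm_coupled: float = 0.3
    beta_5hmc: float = 0.6
    beta_cn: float = 0.3
    beta_pm: float = -0.3
    beta_snv: float = 0.2
    beta_sv: float = 0.2
    noise_sd: float = 0.8
    nb_dispersion: float = 0.3
    seed: int = 0
    survival_baseline_hazard: float = 0.02  # events per month
    censor_window_months: float = 72.0
    planted_log_hr: dict = field(
        default_factory=lambda: {"ct_fraction": 1.5})

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        if self.n_samples < 3:
            raise ValidationError("n_samples must be >= 3")
        for name in ("frac_5hmc_coupled", "frac_pm_coupled"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted parameters of a generated cohort."""

    beta: pd.DataFrame           # per-gene effective effect sizes, one col/layer
    noise_sd: float
    ct_fraction: pd.Series       # per sample, in [0, 1]
    tissue_weights: pd.DataFrame  # sample x tissue, rows on the simplex
    hazard: pd.Series            # per-sample true event hazard (per month)
    coupled_genes: list[str]
    pm_coupled_genes: list[str]

    def analytic_partial_r2(self) -> pd.Series:
        """Closed-form partial R^2 of the 5hmC term under the generative model.

        All generative predictors are standardized and independent, so the
        population R^2 gained by adding the 5hmC term is
        ``beta_5hmc^2 / (sum_j beta_j^2 + noise_sd^2)`` per gene.
        """
        total = (self.beta ** 2).sum(axis=1) + self.noise_sd ** 2
        return self.beta["beta_5hmc"] ** 2 / total


def _zscore(a: np.ndarray, axis: int = 1) -> np.ndarray:
    m = a.mean(axis=axis, keepdims=True)
    s = a.std(axis=axis, ddof=1, keepdims=True)
    s = np.where(s > 0, s, np.nan)
    return (a - m) / s


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _gene_model(rng: np.random.Generator, n_genes: int) -> pd.DataFrame:
    lengths = np.round(rng.lognormal(np.log(20_000), 0.8, n_genes)).astype(int)
    lengths = np.clip(lengths, 1000, 2_000_000)
    chroms = [f"chr{1 + i % 22}" for i in range(n_genes)]
    starts = np.zeros(n_genes, dtype=int)
    cursor: dict[str, int] = {}
    for i, c in enumerate(chroms):
        pos = cursor.get(c, 10_000)
        starts[i] = pos
        cursor[c] = pos + lengths[i] + int(rng.integers(5_000, 50_000))
    strands = rng.choice(["+", "-"], n_genes)
    return pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(n_genes)],
        "chrom": chroms,
        "start": starts,
        "end": starts + lengths,
        "strand": strands,
        "biotype": "protein_coding",
        "length": lengths,
    })


def _sample_meta(rng: np.random.Generator, samples: list[str],
                 ct_fraction: np.ndarray) -> pd.DataFrame:
    n = len(samples)
    return pd.DataFrame({
        "state": "mCRPC",
        "tumor_purity": rng.uniform(0.2, 0.9, n),
        "t2e": rng.integers(0, 2, n).astype(bool),
        "t_scnc": rng.random(n) < 0.04,
        "ct_fraction": ct_fraction,
        "age_at_mcrpc": rng.normal(68, 8, n),
        "psa_at_arsi": rng.lognormal(np.log(30), 1.0, n),
        "hb_at_arsi": rng.normal(13, 1.5, n),
        "arsi_type": rng.integers(0, 2, n),       # 0 abiraterone, 1 enzalutamide
        "prior_docetaxel": rng.random(n) < 0.3,
        "time_to_crpc_months": rng.lognormal(np.log(18), 0.6, n),
        "visceral_mets": rng.random(n) < 0.25,
    }, index=pd.Index(samples, name="sample_id"))


def generate_survival(covariates: pd.DataFrame, planted_log_hr: dict,
                      baseline_hazard: float, censor_window: float,
                      seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Exponential proportional-hazards survival with planted log-hazards.

    The linear predictor sums ``planted_log_hr[name] * covariates[name]``
    (covariates entered on their native scale); censoring is uniform over
    ``(0, censor_window]``.  Returns (frame with time/event, true hazards).
    """
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(covariates))
    for name, loghr in planted_log_hr.items():
        if name not in covariates.columns:
            raise ValidationError(f"planted covariate {name!r} not in table")
        lp = lp + loghr * covariates[name].to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0, censor_window, len(covariates))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    frame = pd.DataFrame({"time": time, "event": event}, index=covariates.index)
    return frame, pd.Series(hazard, index=covariates.index, name="hazard")


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, OmicsBundle, GroundTruth]:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G, N = config.n_genes, config.n_samples
    genes = _gene_model(rng, G)
    gene_ids = genes["gene_id"].to_numpy()
    samples = [f"S{i:04d}" for i in range(N)]

    # 5hmC counts: NB, mean proportional to gene length and library size
    base_rate = rng.lognormal(np.log(5.0), 1.0, G)
    size_factor = rng.lognormal(0.0, 0.2, N)
    mean = np.outer(base_rate * genes["length"].to_numpy() / 1000.0, size_factor)
    counts = _negative_binomial(rng, mean, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    tpm = tpm_normalize(counts_df, genes.set_index("gene_id")["length"]
                        .reindex(gene_ids))
    h = np.log2(tpm.to_numpy() + 1.0)
    h_z = _zscore(h)
    h_z = np.nan_to_num(h_z)

    # planted effect assignment
    n_coupled = int(round(config.frac_5hmc_coupled * G))
    coupled = rng.choice(G, n_coupled, replace=False)
    n_pm = int(round(config.frac_pm_coupled * G))
    pm_coupled = rng.choice(G, n_pm, replace=False)
    beta_h = np.zeros(G)
    beta_h[coupled] = config.beta_5hmc
    beta_pm = np.zeros(G)
    beta_pm[pm_coupled] = config.beta_pm
    beta_cn = np.full(G, config.beta_cn)

    # promoter methylation: Gaussian latent entering the model, Beta marginal
    pm_z = rng.standard_normal((G, N))
    pm_obs = stats.beta.ppf(stats.norm.cdf(pm_z), 2.0, 2.0)

    # copy number: continuous around diploid
    cn_z = rng.standard_normal((G, N))
    cn_obs = 2.0 + 0.5 * cn_z

    # sparse variant indicators; effective beta zeroed where cohort-constant
    snv = rng.binomial(1, 0.05, (G, N))
    sv = rng.binomial(1, 0.02, (G, N))
    beta_snv = np.full(G, config.beta_snv)
    beta_sv = np.full(G, config.beta_sv)

    def _z_or_drop(x, beta_vec):
        out = np.zeros_like(x, dtype=float)
        for g in range(G):
            sd = x[g].std(ddof=1)
            if sd > 0:
                out[g] = (x[g] - x[g].mean()) / sd
            else:
                beta_vec[g] = 0.0
        return out

    snv_z = _z_or_drop(snv, beta_snv)
    sv_z = _z_or_drop(sv, beta_sv)

    noise = rng.normal(0, config.noise_sd, (G, N))
    baseline = rng.normal(6.0, 1.0, G)[:, None]
    expr_log = (baseline
                + beta_h[:, None] * h_z
                + beta_pm[:, None] * pm_z
                + beta_cn[:, None] * cn_z
                + beta_snv[:, None] * snv_z
                + beta_sv[:, None] * sv_z
                + noise)
    expr_tpm = np.clip(np.exp2(expr_log) - 1.0, 0.0, None)

    ct_fraction = rng.beta(2.0, 3.0, N)
    tissue_weights = rng.dirichlet([4.0, 4.0, 1.0, 1.0, 1.0, 1.0], N)
    meta = _sample_meta(rng, samples, ct_fraction)
    surv_seed = int(rng.integers(0, 2**31 - 1))
    surv, hazard = generate_survival(
        meta, config.planted_log_hr, config.survival_baseline_hazard,
        config.censor_window_months, surv_seed)
    meta["os_months"] = surv["time"]
    meta["os_event"] = surv["event"]

    def _mat(a):
        return pd.DataFrame(a, index=gene_ids, columns=samples)

    bundle = OmicsBundle(
        tpm_5hmc=tpm,
        expr=_mat(expr_tpm),
        promoter_meth=_mat(pm_obs),
        copy_number=_mat(cn_obs),
        snv_count=_mat(snv),
        sv_count=_mat(sv),
        sample_meta=meta,
    ).validate()

    beta_df = pd.DataFrame({
        "beta_5hmc": beta_h, "beta_pm": beta_pm, "beta_cn": beta_cn,
        "beta_snv": beta_snv, "beta_sv": beta_sv,
    }, index=pd.Index(gene_ids, name="gene_id"))
    truth = GroundTruth(
        beta=beta_df,
        noise_sd=config.noise_sd,
        ct_fraction=pd.Series(ct_fraction, index=samples, name="ct_fraction"),
        tissue_weights=pd.DataFrame(tissue_weights, index=samples,
                                    columns=DEFAULT_TISSUES),
        hazard=hazard,
        coupled_genes=[gene_ids[i] for i in sorted(coupled)],
        pm_coupled_genes=[gene_ids[i] for i in sorted(pm_coupled)],
    )
    return genes, bundle, truth


def generate_tissue_panel(n_genes: int = 300,
                          tissues: list[str] | None = None,
                          n_markers: int = 30,
                          seed: int = 0) -> pd.DataFrame:
    """Gene x tissue reference 5hmC profiles with tissue-specific marker blocks.

    Each tissue gets ``n_markers`` genes with elevated signal on top of a
    shared nonnegative background, giving the panel enough contrast for
    reference-based deconvolution.
    """
    tissues = tissues or list(DEFAULT_TISSUES)
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 1.0, (n_genes, len(tissues)))
    for j in range(len(tissues)):
        idx = rng.choice(n_genes, n_markers, replace=False)
        base[idx, j] += rng.gamma(4.0, 2.0, n_markers)
    return pd.DataFrame(base, index=[f"G{i:05d}" for i in range(n_genes)],
                        columns=tissues)


def generate_cfdna_mixture(panel: pd.DataFrame, weights, noise_sd: float,
                           seed: int) -> pd.Series:
    """One cfDNA 5hmC profile as a noisy mixture of panel columns.

    ``profile = panel @ weights + N(0, noise_sd)``, truncated at zero.
    Weights must be a nonnegative simplex vector over the panel's tissues.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (panel.shape[1],):
        raise ValidationError("weights length must equal panel tissue count")
    if (w < 0).any():
        raise ValidationError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    profile = panel.to_numpy() @ w
    if noise_sd > 0:
        profile = profile + rng.normal(0, noise_sd, len(profile))
    return pd.Series(np.clip(profile, 0, None), index=panel.index,
                     name="profile")


def expected_vaf(true_ct: float, loh: bool = True) -> float:
    """Expected somatic VAF at tumor fraction t.

    With associated one-copy loss (LOH) the mutant allele is the only tumor
    copy: VAF = t / (2 - t).  Without LOH (heterozygous diploid): VAF = t / 2.
    """
    if not 0 <= true_ct <= 1:
        raise ValidationError("true_ct must be in [0, 1]")
    return true_ct / (2.0 - true_ct) if loh else true_ct / 2.0


def generate_variant_reads(true_ct: float, depth: int, loh: bool = True,
                           n_variants: int = 50, seed: int = 0,
                           background_error: float = 5e-4,
                           include_decoys: bool = True) -> pd.DataFrame:
    """Simulate a cfDNA variant table at a known tumor fraction.

    Alt read counts are binomial at the copy-model VAF plus background error.
    When ``include_decoys`` is set the table also carries variants on
    amplified genes (copy log-ratio > 0.2) and on allosomes with inflated
    VAFs, which surrogate selection must exclude.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    p = min(expected_vaf(true_ct, loh) + background_error, 1.0)
    rows = []

    def _row(i, chrom, vaf_p, log_ratio):
        alt = rng.binomial(depth, vaf_p)
        germ_alt = rng.binomial(depth, background_error)
        return {
            "chrom": chrom, "pos": 1_000_000 + 1000 * i, "ref": "C", "alt": "T",
            "unique_read_support": int(alt), "vaf": alt / depth,
            "mapq_mean": float(rng.normal(55, 3)),
            "background_error": float(abs(rng.normal(background_error,
                                                     background_error / 5))),
            "germline_vaf": germ_alt / depth,
            "leukocyte_depth": int(max(20, rng.poisson(depth / 2))),
            "gene": f"GENE{i:03d}", "copy_log_ratio": float(log_ratio),
            "consequence": "missense", "population_freq": 0.0,
        }

    for i in range(n_variants):
        lr = float(np.clip(rng.normal(0, 0.05), None, 0.2))
        rows.append(_row(i, f"chr{1 + i % 22}", p, lr))
    if include_decoys:
        amp_p = min(1.5 * p + background_error, 0.95)
        allo_p = min(2.0 * p + background_error, 0.95)
        rows.append(_row(n_variants, "chr8", amp_p, 0.5))
        rows.append(_row(n_variants + 1, "chrX", allo_p, 0.0))
    return pd.DataFrame(rows)


def write_cohort(outdir, genes: pd.DataFrame, bundle: OmicsBundle,
                 truth: GroundTruth, config: CohortConfig | None = None) -> None:
    """Write a generated cohort as TSV tables plus a JSON ground-truth sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes.to_csv(outdir / "gene_model.tsv", sep="\t", index=False)
    for name, mat in bundle.matrices().items():
        write_matrix(mat, outdir / f"{name}.tsv")
    bundle.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t")
    sidecar = {
        "noise_sd": truth.noise_sd,
        "beta": {c: truth.beta[c].tolist() for c in truth.beta.columns},
        "gene_ids": truth.beta.index.tolist(),
        "ct_fraction": truth.ct_fraction.tolist(),
        "tissue_weights": truth.tissue_weights.to_numpy().tolist(),
        "tissues": truth.tissue_weights.columns.tolist(),
        "hazard": truth.hazard.tolist(),
        "coupled_genes": truth.coupled_genes,
        "pm_coupled_genes": truth.pm_coupled_genes,
    }
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    write_json(sidecar, outdir / "ground_truth.json")
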