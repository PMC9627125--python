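"""Integrative per-gene expression modeling.

For every gene, expression (z-scored log2(TPM+1)) is modeled by ordinary
least squares on five layers: z-scored log2(TPM+1) gene-body 5hmC, promoter
CpG methylation, gene copy number, and SNV / SV counts.  The added
explanatory value of 5hmC is the difference in adjusted R^2 between the full
model and the nested model without the 5hmC term; its significance is the
partial F-test of that comparison (identical to the two-sided t-test on the
5hmC coefficient for a single added regressor), with Benjamini-Hochberg
control across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .quantify import OmicsBundle

PREDICTORS = ["x_5hmc", "x_pm", "x_cn", "x_snv", "x_sv"]

FIT_COLUMNS = ["beta_5hmc", "beta_pm", "beta_cn", "beta_snv", "beta_sv",
               "adj_r2_with", "adj_r2_without", "r2_with", "r2_without",
               "p_5hmc", "n_samples"]


def log2_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    return np.log2(matrix + 1.0)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    m = matrix.mean(axis=1)
    s = matrix.std(axis=1, ddof=1)
    return matrix.sub(m, axis=0).div(s.where(s > 0), axis=0)


def _design(bundle: OmicsBundle) -> dict[str, pd.DataFrame]:
    """Shared transforms: scaled 5hmC and expression, raw other layers."""
    out = {
        "y": zscore_rows(log2_tpm(bundle.expr)),
        "x_5hmc": zscore_rows(log2_tpm(bundle.tpm_5hmc)),
    }
    for key, mat in (("x_pm", bundle.promoter_meth),
                     ("x_cn", bundle.copy_number),
                     ("x_snv", bundle.snv_count),
                     ("x_sv", bundle.sv_count)):
        out[key] = mat if mat is not None else None
    return out


def per_gene_correlations(bundle: OmicsBundle) -> pd.DataFrame:
    """Spearman correlation of expression with each layer, per gene.

    Genes with missing data in a pair or without variation in either member
    get NaN for that layer.  Columns: rho_5hmc, rho_cn, rho_pm.
    """
    bundle.validate()
    expr = log2_tpm(bundle.expr)
    layers = {"rho_5hmc": log2_tpm(bundle.tpm_5hmc),
              "rho_cn": bundle.copy_number,
              "rho_pm": bundle.promoter_meth}
    out = pd.DataFrame(np.nan, index=expr.index,
                       columns=[k for k, v in layers.items() if v is not None])
    e = expr.to_numpy()
    for name, mat in layers.items():
        if mat is None:
            continue
        x = mat.to_numpy()
        vals = np.full(expr.shape[0], np.nan)
        for g in range(expr.shape[0]):
            mask = ~(np.isnan(e[g]) | np.isnan(x[g]))
            if mask.sum() < 3:
                continue
            ye, xe = e[g, mask], x[g, mask]
            if np.ptp(ye) == 0 or np.ptp(xe) == 0:
                continue
            vals[g] = stats.spearmanr(xe, ye).statistic
        out[name] = vals
    return out


@dataclass
class GeneFit:
    """OLS fit of one gene's expression on the omic layers."""

    gene_id: str
    params: pd.Series
    adj_r2_with: float
    adj_r2_without: float
    r2_with: float
    r2_without: float
    p_5hmc: float
    n_samples: int
    dropped_terms: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "beta_5hmc": self.params.get("x_5hmc", np.nan),
            "beta_pm": self.params.get("x_pm", np.nan),
            "beta_cn": self.params.get("x_cn", np.nan),
            "beta_snv": self.params.get("x_snv", np.nan),
            "beta_sv": self.params.get("x_sv", np.nan),
            "adj_r2_with": self.adj_r2_with,
            "adj_r2_without": self.adj_r2_without,
            "r2_with": self.r2_with,
            "r2_without": self.r2_without,
            "p_5hmc": self.p_5hmc,
            "n_samples": self.n_samples,
        }


def fit_expression_model(y: pd.Series, predictors: pd.DataFrame,
                         gene_id: str = "") -> GeneFit | None:
    """Fit one gene: OLS of scaled expression on the layer predictors.

    Samples with any missing value are dropped listwise; predictors that are
    constant in the remaining samples carry no information and are dropped
    from the design.  Returns ``None`` (fit flagged missing) when fewer than
    p + 2 complete samples remain, the response is constant, or the design is
    rank-deficient after constant removal.
    """
    frame = pd.concat([y.rename("y"), predictors], axis=1).dropna()
    n = len(frame)
    if "x_5hmc" not in predictors.columns:
        raise ValidationError("predictors must include x_5hmc")
    yv = frame["y"].to_numpy(dtype=float)
    if n == 0 or np.ptp(yv) == 0:
        return None
    keep = [c for c in predictors.columns
            if np.ptp(frame[c].to_numpy(dtype=float)) > 0]
    dropped = tuple(c for c in predictors.columns if c not in keep)
    if "x_5hmc" not in keep or n < len(keep) + 2:
        return None
    X = sm.add_constant(frame[keep].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    full = sm.OLS(yv, X).fit()
    idx_h = keep.index("x_5hmc") + 1  # after the constant
    X0 = np.delete(X, idx_h, axis=1)
    reduced = sm.OLS(yv, X0).fit()
    params = pd.Series(full.params[1:], index=keep)
    return GeneFit(
        gene_id=gene_id,
        params=params,
        adj_r2_with=float(full.rsquared_adj),
        adj_r2_without=float(reduced.rsquared_adj),
        r2_with=float(full.rsquared),
        r2_without=float(reduced.rsquared),
        p_5hmc=float(full.pvalues[idx_h]),
        n_samples=n,
        dropped_terms=dropped,
    )


class IntegrationResults:
    """Per-gene fits plus cohort-level summaries."""

    def __init__(self, table: pd.DataFrame, fdr_threshold: float = 0.05):
        self.table = table
        self.fdr_threshold = fdr_threshold

    @property
    def fitted(self) -> pd.DataFrame:
        return self.table.dropna(subset=["p_5hmc"])

    def summary(self) -> dict:
        fitted = self.fitted
        return {
            "n_genes": int(len(self.table)),
            "n_fitted": int(len(fitted)),
            "median_adj_r2_with": float(fitted["adj_r2_with"].median()),
            "median_adj_r2_without": float(fitted["adj_r2_without"].median()),
            "median_delta_adj_r2": float(
                (fitted["adj_r2_with"] - fitted["adj_r2_without"]).median()),
            "n_significant": int((fitted["q_5hmc"] <= self.fdr_threshold).sum()),
            "fdr_threshold": self.fdr_threshold,
        }


def fit_all_genes(bundle: OmicsBundle,
                  fdr_threshold: float = 0.05) -> IntegrationResults:
    """Fit every gene and BH-adjust the 5hmC term p-values across genes."""
    bundle.validate()
    design = _design(bundle)
    y_all = design["y"]
    pred_mats = {k: design[k] for k in PREDICTORS if design[k] is not None}
    rows = {}
    for gene in y_all.index:
        preds = pd.DataFrame({k: m.loc[gene] for k, m in pred_mats.items()})
        fit = fit_expression_model(y_all.loc[gene], preds, gene_id=gene)
        rows[gene] = (fit.as_row() if fit is not None
                      else dict.fromkeys(FIT_COLUMNS, np.nan))
    table = pd.DataFrame.from_dict(rows, orient="index")[FIT_COLUMNS]
    table.index.name = "gene_id"
    mask = table["p_5hmc"].notna()
    q = np.full(len(table), np.nan)
    if mask.any():
        q[mask.to_numpy()] = multipletests(
            table.loc[mask, "p_5hmc"], method="fdr_bh")[1]
    table["q_5hmc"] = q
    return IntegrationResults(table, fdr_threshold)


def coefficient_group_test(fits: pd.DataFrame, gene_set) -> dict:
    """Two-sided Wilcoxon rank-sum of scaled 5hmC coefficients, set vs rest."""
    fitted = fits.dropna(subset=["beta_5hmc"])
    in_mask = fitted.index.isin(set(gene_set))
    b_in = fitted.loc[in_mask, "beta_5hmc"]
    b_out = fitted.loc[~in_mask, "beta_5hmc"]
    if len(b_in) == 0:
        raise ValidationError("gene set does not overlap fitted genes")
    if len(b_out) == 0:
        raise ValidationError("gene set leaves an empty complement")
    res = stats.mannwhitneyu(b_in, b_out, alternative="two-sided")
    return {"median_in": float(b_in.median()),
            "median_out": float(b_out.median()),
            "n_in": int(len(b_in)), "n_out": int(len(b_out)),
            "p": float(res.pvalue)}
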