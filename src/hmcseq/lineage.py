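"""Reference-based tissue-composition scoring of 5hmC profiles.

A sample profile is decomposed over a gene x tissue reference panel by
nonnegative least squares after per-gene standardization against the panel
(standardization is linear per gene, so simplex mixtures of panel columns are
preserved exactly and recovered exactly in the noise-free case).  Weights are
normalized to the simplex and reported as tissue scores; the GI score is the
summed weight of the gastrointestinal tissues (colon, gastric, liver,
pancreatic) and flags gastrointestinal lineage plasticity at >= 0.25.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .enrich import gsea_preranked
from .errors import ValidationError

GI_TISSUES = ["colon", "gastric", "liver", "pancreatic"]
GI_THRESHOLD = 0.25


def _standardize_panel(panel: pd.DataFrame):
    a = panel.to_numpy(dtype=float)
    m = a.mean(axis=1)
    s = a.std(axis=1, ddof=1)
    keep = s > 0
    return a[keep], m[keep], s[keep], keep


def tissue_scores(profile: pd.Series | pd.DataFrame, panel: pd.DataFrame,
                  log_transform: bool = False,
                  min_shared_genes: int = 50) -> pd.Series | pd.DataFrame:
    """Simplex tissue weights of one or many 5hmC profiles.

    Parameters
    ----------
    profile : Series (one sample) or genes x samples DataFrame
        5hmC profile(s) on the same scale as the panel.
    panel : genes x tissues DataFrame
        Nonnegative reference profiles, >= 2 tissues.
    log_transform : bool
        Apply log2(x + 1) to profile and panel first; use for raw TPM-scale
        inputs.  Off by default so that linear mixtures of panel columns are
        recovered exactly.
    """
    if panel.shape[1] < 2:
        raise ValidationError("panel needs at least 2 tissues")
    if (panel.to_numpy() < 0).any():
        raise ValidationError("panel entries must be nonnegative")
    single = isinstance(profile, pd.Series)
    prof = profile.to_frame() if single else profile
    shared = panel.index.intersection(prof.index)
    if len(shared) < min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared between profile and panel "
            f"(need >= {min_shared_genes})")
    a = panel.loc[shared]
    b = prof.loc[shared]
    if log_transform:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    A, m, s, keep = _standardize_panel(a)
    A = (A - m[:, None]) / s[:, None]
    # Row-centering makes the columns sum to the zero vector, so the simplex
    # direction is unidentified from the data rows alone; append a
    # sum-to-one row to pin it.  A true simplex mixture satisfies the
    # appended row exactly, so noise-free recovery stays exact.
    lam = np.sqrt(A.shape[0])
    A_aug = np.vstack([A, lam * np.ones(panel.shape[1])])
    degenerate = np.linalg.matrix_rank(A_aug) < panel.shape[1]
    if degenerate:
        warnings.warn("tissue panel is collinear; falling back to "
                      "pseudo-inverse weights", stacklevel=2)
        pinv = np.linalg.pinv(A_aug)
    out = {}
    for col in b.columns:
        bv = (b[col].to_numpy(dtype=float)[keep] - m) / s
        bv_aug = np.append(bv, lam)
        if degenerate:
            w = np.clip(pinv @ bv_aug, 0, None)
        else:
            w, _ = nnls(A_aug, bv_aug)
        total = w.sum()
        if total <= 0:
            raise ValidationError(
                f"profile {col!r} has no nonnegative projection on the panel")
        out[col] = w / total
    scores = pd.DataFrame(out, index=panel.columns).T
    scores.index.name = "sample_id"
    return scores.iloc[0] if single else scores


def gi_score(scores: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Summed tissue weight of colon + gastric + liver + pancreatic."""
    cols = scores.index if isinstance(scores, pd.Series) else scores.columns
    missing = [t for t in GI_TISSUES if t not in cols]
    if missing:
        raise ValidationError(f"GI tissues missing from scores: {missing}")
    if isinstance(scores, pd.Series):
        return float(scores[GI_TISSUES].sum())
    return scores[GI_TISSUES].sum(axis=1).rename("gi_score")


def classify_gi(score, threshold: float = GI_THRESHOLD):
    """Flag gastrointestinal lineage at GI score >= threshold."""
    if isinstance(score, pd.Series):
        return score >= threshold
    return bool(score >= threshold)


def gi_expression_concordance(gi_scores: pd.Series, expr: pd.DataFrame,
                              gene_set, set_name: str = "pca_gi",
                              n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Enrichment of a gene set among genes ranked by correlation with GI score.

    Per gene, the Spearman correlation of expression with the per-sample GI
    score; the signed correlations form the ranking handed to
    :func:`hmcseq.enrich.gsea_preranked`.
    """
    shared = expr.columns.intersection(gi_scores.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples")
    g = gi_scores.loc[shared].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise ValidationError("GI score is constant; correlations undefined")
    e = expr[shared].to_numpy(dtype=float)
    rho = np.full(expr.shape[0], np.nan)
    for i in range(expr.shape[0]):
        if np.ptp(e[i]) > 0:
            rho[i] = stats.spearmanr(e[i], g).statistic
    ranked = pd.Series(rho, index=expr.index).dropna()
    return gsea_preranked(ranked, {set_name: list(gene_set)},
                          n_perm=n_perm, seed=seed)
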