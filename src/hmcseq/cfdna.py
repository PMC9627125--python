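"""cfDNA 5hmC classifiers: tumor-fraction regression and driver-event scores.

The tumor-fraction (ct) classifier selects genes whose gene-body 5hmC levels
track tumor cell content in tissue (correlation test at P <= 0.05 and
Bonferroni-adjusted q <= 1e-5), then fits an elastic-net linear model on the
selected genes; predictions are clipped to [0, 1].

The driver-event score counts quartile-inferred gains of the oncogenes AR,
MYC and NCOA2 (gene-body 5hmC in the upper quartile across samples) and
losses of the tumor suppressors RB1, PTEN, TP53, BRCA2 and NKX3-1 (lowest
quartile), binned 0-1 / 2-3 / >3.  The TOP2A/EZH2 class marks samples in the
top quartile for none, either, or both genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import ValidationError

SELECT_P = 0.05
SELECT_BONFERRONI_Q = 1e-5

ONCOGENES = ["AR", "MYC", "NCOA2"]
SUPPRESSORS = ["RB1", "PTEN", "TP53", "BRCA2", "NKX3-1"]
EVENT_BINS = ["0-1", "2-3", ">3"]

L1_RATIO_GRID = [0.1, 0.5, 0.9]


def _log2p1(m):
    return np.log2(m + 1.0)


def select_ct_genes(tpm_5hmc: pd.DataFrame, purity: pd.Series,
                    method: str = "pearson") -> list[str]:
    """Genes whose 5hmC levels correlate with tissue tumor cell content.

    Per-gene correlation test of log2(TPM+1) against purity; a gene is kept
    when its p-value passes both P <= 0.05 and the Bonferroni-adjusted
    q = min(1, p * n_genes) <= 1e-5.  Pearson by default (the downstream
    model is linear); ``method="spearman"`` is available.
    """
    purity = purity.reindex(tpm_5hmc.columns).dropna()
    if len(purity) < 10:
        raise ValidationError("need >= 10 samples with purity values")
    if np.ptp(purity.to_numpy(dtype=float)) == 0:
        raise ValidationError("purity is constant; correlation undefined")
    x = _log2p1(tpm_5hmc[purity.index]).to_numpy(dtype=float)
    pv = purity.to_numpy(dtype=float)
    G = x.shape[0]
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    selected = []
    for g, gene in enumerate(tpm_5hmc.index):
        if np.ptp(x[g]) == 0:
            continue
        p = corr_fn(x[g], pv).pvalue
        if p <= SELECT_P and min(1.0, p * G) <= SELECT_BONFERRONI_Q:
            selected.append(gene)
    return selected


@dataclass
class CtClassifier:
    """Elastic-net linear model from selected 5hmC genes to tumor fraction."""

    genes: list[str]
    coef: np.ndarray
    intercept: float
    feature_means: pd.Series      # training means, used to impute missing genes
    alpha: float
    l1_ratio: float
    folds: int
    seed: int
    selection_thresholds: dict = field(
        default_factory=lambda: {"p": SELECT_P, "bonferroni_q": SELECT_BONFERRONI_Q})

    def to_json(self, path) -> None:
        obj = {"genes": list(self.genes), "coef": list(map(float, self.coef)),
               "intercept": float(self.intercept),
               "feature_means": {g: float(v)
                                 for g, v in self.feature_means.items()},
               "alpha": float(self.alpha), "l1_ratio": float(self.l1_ratio),
               "folds": self.folds, "seed": self.seed,
               "selection_thresholds": self.selection_thresholds}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CtClassifier":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(genes=obj["genes"], coef=np.asarray(obj["coef"]),
                   intercept=obj["intercept"],
                   feature_means=pd.Series(obj["feature_means"]),
                   alpha=obj["alpha"], l1_ratio=obj["l1_ratio"],
                   folds=obj["folds"], seed=obj["seed"],
                   selection_thresholds=obj["selection_thresholds"])


def train_ct_model(tpm_5hmc: pd.DataFrame, purity: pd.Series,
                   folds: int = 5, seed: int = 0) -> CtClassifier:
    """Fit the elastic-net ct model on log2(TPM+1) of the selected genes.

    Penalty mix chosen by cross-validated MSE over l1_ratio {0.1, 0.5, 0.9}
    and the automatic lambda path; deterministic given the seed.
    """
    if tpm_5hmc.shape[0] == 0:
        raise ValidationError("no selected genes to train on")
    purity = purity.reindex(tpm_5hmc.columns)
    if purity.isna().any():
        raise ValidationError("purity missing for some training samples")
    if len(purity) < folds:
        raise ValidationError(f"fewer samples ({len(purity)}) than folds ({folds})")
    X = _log2p1(tpm_5hmc).to_numpy(dtype=float).T
    y = purity.to_numpy(dtype=float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(l1_ratio=L1_RATIO_GRID, cv=cv, random_state=seed,
                         max_iter=50_000)
    model.fit(X, y)
    return CtClassifier(
        genes=list(tpm_5hmc.index), coef=model.coef_,
        intercept=float(model.intercept_),
        feature_means=pd.Series(X.mean(axis=0), index=tpm_5hmc.index),
        alpha=float(model.alpha_), l1_ratio=float(model.l1_ratio_),
        folds=folds, seed=seed)


def predict_ct(model: CtClassifier,
               profile: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Predict tumor fraction from a 5hmC TPM profile, clipped to [0, 1].

    Genes absent from the profile are imputed at their training mean; more
    than 20% missing is an error.
    """
    single = isinstance(profile, pd.Series)
    prof = profile.to_frame() if single else profile
    present = prof.index.intersection(model.genes)
    n_missing = len(model.genes) - len(present)
    if n_missing > 0.2 * len(model.genes):
        raise ValidationError(
            f"{n_missing}/{len(model.genes)} model genes missing from profile")
    X = _log2p1(prof.reindex(model.genes)).T
    for gene in model.genes:
        if X[gene].isna().any():
            X[gene] = X[gene].fillna(model.feature_means[gene])
    pred = X.to_numpy(dtype=float) @ model.coef + model.intercept
    pred = np.clip(pred, 0.0, 1.0)
    out = pd.Series(pred, index=prof.columns, name="predicted_ct")
    return float(out.iloc[0]) if single else out


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    return (float(np.quantile(values, 0.25)), float(np.quantile(values, 0.75)))


def _event_bin(events: int) -> str:
    if events <= 1:
        return "0-1"
    if events <= 3:
        return "2-3"
    return ">3"


def driver_event_score(tpm_5hmc: pd.DataFrame) -> pd.DataFrame:
    """Quartile-inferred driver events per sample from gene-body 5hmC.

    Oncogene gained if its value is >= the across-sample upper quartile;
    suppressor lost if <= the lower quartile.  Returns per-gene flags, the
    event count (0-8) and its bin.
    """
    missing = [g for g in ONCOGENES + SUPPRESSORS if g not in tpm_5hmc.index]
    if missing:
        raise ValidationError(f"driver gene(s) missing from matrix: {missing}")
    flags = {}
    for gene in ONCOGENES:
        vals = tpm_5hmc.loc[gene].to_numpy(dtype=float)
        _, q3 = _quartiles(vals)
        flags[f"{gene}_gain"] = vals >= q3
    for gene in SUPPRESSORS:
        vals = tpm_5hmc.loc[gene].to_numpy(dtype=float)
        q1, _ = _quartiles(vals)
        flags[f"{gene}_loss"] = vals <= q1
    out = pd.DataFrame(flags, index=tpm_5hmc.columns)
    out["events"] = out.sum(axis=1).astype(int)
    out["bin"] = pd.Categorical([_event_bin(e) for e in out["events"]],
                                categories=EVENT_BINS, ordered=True)
    out.index.name = "sample_id"
    return out


def top2a_ezh2_class(tpm_5hmc: pd.DataFrame,
                     genes: tuple[str, str] = ("TOP2A", "EZH2")) -> pd.Series:
    """Top-quartile membership class for TOP2A/EZH2: none, either, or both."""
    missing = [g for g in genes if g not in tpm_5hmc.index]
    if missing:
        raise ValidationError(f"gene(s) missing from matrix: {missing}")
    count = np.zeros(tpm_5hmc.shape[1], dtype=int)
    for gene in genes:
        vals = tpm_5hmc.loc[gene].to_numpy(dtype=float)
        _, q3 = _quartiles(vals)
        count += (vals >= q3).astype(int)
    labels = np.array(["none", "either", "both"])[count]
    return pd.Series(pd.Categorical(labels, categories=["none", "either", "both"],
                                    ordered=True),
                     index=tpm_5hmc.columns, name="top2a_ezh2_class")
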