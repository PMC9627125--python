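"""Kaplan-Meier and Cox proportional-hazards analyses of 5hmC-derived scores.

Thin, validated wrappers around lifelines (Efron tie handling, lifelines'
default) exposing the analyses the 5hmC scores feed into: tertile splits of
predicted tumor fraction, per-group product-limit curves, Cox hazard ratios
with Wald tests, and the per-event hazard ratio of the driver-event score
unadjusted and adjusted for tumor fraction plus the clinical covariate block
(age at mCRPC diagnosis, PSA and hemoglobin at first-line ARSI, ARSI type,
prior docetaxel, time to CRPC from ADT start, visceral metastases).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from .errors import ConvergenceError, ValidationError

CLINICAL_COVARIATES = [
    "age_at_mcrpc", "psa_at_arsi", "hb_at_arsi", "arsi_type",
    "prior_docetaxel", "time_to_crpc_months", "visceral_mets",
]
TERTILE_LABELS = ["low", "mid", "high"]


def tertile_split(values: pd.Series) -> pd.Series:
    """Split samples into tertiles (low/mid/high), boundaries to the lower group."""
    v = values.dropna()
    if len(v) < 3:
        raise ValidationError("need >= 3 samples to split into tertiles")
    arr = v.to_numpy(dtype=float)
    if len(np.unique(arr)) < 3:
        raise ValidationError("need >= 3 distinct values to split into tertiles")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    labels = np.where(arr <= q1, "low", np.where(arr <= q2, "mid", "high"))
    out = pd.Series(pd.Categorical(labels, categories=TERTILE_LABELS,
                                   ordered=True), index=v.index, name="tertile")
    return out.reindex(values.index)


def km_fit(records: pd.DataFrame, groups: pd.Series | None = None,
           time_col: str = "time", event_col: str = "event") -> dict:
    """Product-limit survival curves, per group when groups are given.

    Returns ``{"curves": {group: DataFrame(time, survival)}, "n": {...},
    "events": {...}}``; curves are right-continuous steps with S(0) = 1.
    """
    if (records[time_col] < 0).any():
        raise ValidationError("negative survival times")
    if groups is None:
        groups = pd.Series("all", index=records.index)
    groups = groups.reindex(records.index)
    curves, ns, events = {}, {}, {}
    for label, idx in groups.groupby(groups, observed=True).groups.items():
        sub = records.loc[idx]
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col])
        sf = km.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
        ns[label] = int(len(sub))
        events[label] = int(sub[event_col].sum())
    return {"curves": curves, "n": ns, "events": events}


def cox_fit(records: pd.DataFrame, predictors: list[str],
            time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Cox proportional hazards (Efron ties) on the named predictors.

    Returns one row per predictor: coef, HR = exp(coef), 95% CI from the
    observed information, and the two-sided Wald p-value.
    """
    frame = records[[time_col, event_col] + list(predictors)].dropna()
    frame = frame.astype(float)
    n_events = int(frame[event_col].sum())
    if n_events < len(predictors):
        raise ValidationError(
            f"{n_events} events for {len(predictors)} predictors")
    for p in predictors:
        if np.ptp(frame[p].to_numpy()) == 0:
            raise ValidationError(f"predictor {p!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col=time_col, event_col=event_col)
    except _LLConvergenceError as exc:
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame({
        "coef": s["coef"],
        "hr": np.exp(s["coef"]),
        "hr_ci_low": np.exp(s["coef lower 95%"]),
        "hr_ci_high": np.exp(s["coef upper 95%"]),
        "se": s["se(coef)"],
        "p": s["p"],
    })
    out.index.name = "predictor"
    return out


def km_group_comparison(records: pd.DataFrame, groups: pd.Series,
                        time_col: str = "time",
                        event_col: str = "event") -> dict:
    """KM curves per group plus a Wald comparison via Cox on the group code.

    Ordered categorical groups enter as a single ordinal term (hazard ratio
    per step); unordered groups as indicator contrasts against the first.
    """
    km = km_fit(records, groups, time_col, event_col)
    groups = groups.reindex(records.index)
    if isinstance(groups.dtype, pd.CategoricalDtype) and groups.cat.ordered:
        codes = pd.Series(groups.cat.codes.astype(float), index=groups.index,
                          name="group_code")
        frame = records[[time_col, event_col]].join(codes)
        cox = cox_fit(frame, ["group_code"], time_col, event_col)
    else:
        dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
        frame = records[[time_col, event_col]].join(dummies)
        cox = cox_fit(frame, list(dummies.columns), time_col, event_col)
    km["cox"] = cox
    return km


def adjusted_event_hr(records: pd.DataFrame, event_score: pd.Series,
                      covariates: list[str] | None = None,
                      time_col: str = "time",
                      event_col: str = "event") -> dict:
    """Hazard ratio per additional driver event, unadjusted and adjusted.

    The score enters the Cox model as a linear term; the adjusted fit adds
    tumor fraction and the clinical covariate block (any of the standard
    covariates present in ``records``, unless an explicit list is given).
    """
    frame = records.copy()
    frame["event_score"] = event_score.reindex(frame.index).astype(float)
    unadj = cox_fit(frame, ["event_score"], time_col, event_col)
    if covariates is None:
        covariates = [c for c in ["ct_fraction"] + CLINICAL_COVARIATES
                      if c in frame.columns]
    adj = cox_fit(frame, ["event_score"] + covariates, time_col, event_col)
    return {
        "unadjusted": unadj.loc["event_score"].to_dict(),
        "adjusted": adj.loc["event_score"].to_dict(),
        "covariates": covariates,
        "n": int(frame[[time_col, event_col, "event_score"]].dropna().shape[0]),
        "events": int(frame[event_col].sum()),
    }
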