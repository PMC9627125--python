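"""Targeted cfDNA sequencing post-processing: filters and ctDNA fraction.

Somatic calls must clear five read-support and error-model rules; the
highest-VAF somatic variant on a non-amplified autosomal gene serves as a
surrogate for total ctDNA content under the conservative assumption of
associated loss of heterozygosity, giving

    ct = 2 / (1 + VAF^-1) = 2 * VAF / (1 + VAF).

Samples with copy-number evidence of tumor content but no passing somatic
variant fall back to heterozygous-SNP allele imbalance in one-copy-loss
genes, inverting f = 1 / (2 - t) to t = 2 - 1/f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

SOMATIC_MIN_READS = 10
SOMATIC_MIN_VAF = 0.01
SOMATIC_MIN_MAPQ = 10          # base substitutions only
SOMATIC_BG_FOLD = 20.0
SOMATIC_GERMLINE_FOLD = 3.0
SOMATIC_MIN_LEUKO_DEPTH = 20

GERMLINE_MIN_READS = 8
GERMLINE_MIN_VAF = 0.10
GERMLINE_MAX_POPFREQ = 0.005
DELETERIOUS_CONSEQUENCES = {"frameshift", "splice_site", "stopgain"}

AMPLIFIED_LOG_RATIO = 0.2
ALLOSOMES = {"chrX", "chrY", "X", "Y"}

# Driver genes whose somatic/germline mutation status the panel reports
MUTATION_PANEL = [
    "AKT1", "APC", "AR", "ATM", "BRCA1", "BRCA2", "CDK12", "CTNNB1", "FOXA1",
    "KMT2C", "KMT2D", "MSH2", "MSH6", "PIK3CA", "PMS2", "PTEN", "RB1", "SPOP",
    "TP53", "ZFHX3",
]
COPY_NUMBER_PANEL = [
    "AR", "ATM", "BRCA1", "BRCA2", "CCND1", "CDK12", "CHD1", "CLU", "MSH2/6",
    "MYC", "NCOA2", "NKX3-1", "PTEN", "RB1", "TP53", "MLH1",
]

_SOMATIC_COLUMNS = ["ref", "alt", "unique_read_support", "vaf", "mapq_mean",
                    "background_error", "germline_vaf", "leukocyte_depth"]


def _is_substitution(df: pd.DataFrame) -> pd.Series:
    return (df["ref"].astype(str).str.len() == 1) \
        & (df["alt"].astype(str).str.len() == 1)


def filter_somatic(variants: pd.DataFrame,
                   return_flags: bool = False) -> pd.DataFrame:
    """Apply the somatic cfDNA variant filters (pure conjunction).

    Rules: >= 10 unique supporting reads; VAF >= 1%; mean mapping quality
    >= 10 for base substitutions; VAF >= 20x the same-position background
    error; VAF >= 3x the paired germline allele frequency; >= 20x raw
    leukocyte depth.  Optional boolean curation columns ``manual_review_fail``
    and ``artifact`` are honored when present (True excludes the row).
    With ``return_flags`` the per-rule pass flags are returned alongside.
    """
    missing = [c for c in _SOMATIC_COLUMNS if c not in variants.columns]
    if missing:
        raise FormatError(f"variant table missing column(s) {missing}")
    flags = pd.DataFrame(index=variants.index)
    flags["pass_reads"] = variants["unique_read_support"] >= SOMATIC_MIN_READS
    flags["pass_vaf"] = variants["vaf"] >= SOMATIC_MIN_VAF
    flags["pass_mapq"] = (~_is_substitution(variants)) \
        | (variants["mapq_mean"] >= SOMATIC_MIN_MAPQ)
    flags["pass_background"] = variants["vaf"] \
        >= SOMATIC_BG_FOLD * variants["background_error"]
    flags["pass_germline"] = variants["vaf"] \
        >= SOMATIC_GERMLINE_FOLD * variants["germline_vaf"]
    flags["pass_leuko_depth"] = variants["leukocyte_depth"] \
        >= SOMATIC_MIN_LEUKO_DEPTH
    for col in ("manual_review_fail", "artifact"):
        if col in variants.columns:
            flags[f"pass_{col}"] = ~variants[col].fillna(False).astype(bool)
    keep = flags.all(axis=1)
    passing = variants.loc[keep].copy()
    if return_flags:
        return passing, flags
    return passing


def filter_germline(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep putatively deleterious germline variants.

    >= 8 unique reads, VAF >= 10%, population frequency < 0.5%, and a
    deleterious consequence (frameshift, splice_site, stopgain).  Rows with a
    consequence string outside the known vocabulary are excluded with a
    warning.
    """
    for col in ("consequence", "population_freq"):
        if col not in variants.columns:
            raise FormatError(f"variant table missing column {col!r}")
    known = DELETERIOUS_CONSEQUENCES | {
        "missense", "synonymous", "nonframeshift", "intronic", "utr", "upstream"}
    unknown = ~variants["consequence"].isin(known)
    if unknown.any():
        import warnings
        warnings.warn(f"excluding {int(unknown.sum())} variant(s) with unknown "
                      "consequence strings", stacklevel=2)
    keep = (variants["unique_read_support"] >= GERMLINE_MIN_READS) \
        & (variants["vaf"] >= GERMLINE_MIN_VAF) \
        & (variants["population_freq"] < GERMLINE_MAX_POPFREQ) \
        & variants["consequence"].isin(DELETERIOUS_CONSEQUENCES)
    return variants.loc[keep].copy()


def select_surrogate(variants: pd.DataFrame) -> pd.Series | None:
    """Highest-VAF somatic variant excluding amplified genes and allosomes.

    Candidates are autosomal with copy log-ratio <= 0.2; ties at the maximum
    VAF break deterministically by (chrom, pos).  Returns the row, or None.
    """
    for col in ("chrom", "copy_log_ratio"):
        if col not in variants.columns:
            raise FormatError(f"variant table missing column {col!r}")
    eligible = variants.loc[
        (~variants["chrom"].astype(str).isin(ALLOSOMES))
        & (variants["copy_log_ratio"] <= AMPLIFIED_LOG_RATIO)]
    if len(eligible) == 0:
        return None
    top = eligible.loc[eligible["vaf"] == eligible["vaf"].max()]
    top = top.sort_values(["chrom", "pos"], kind="mergesort")
    return top.iloc[0]


def ct_fraction_from_vaf(vaf: float) -> float:
    """ctDNA fraction from the surrogate VAF under assumed LOH.

    ct = 2 / (1 + 1/VAF) = 2*VAF / (1 + VAF); 0 at VAF 0, strictly
    increasing, 1 at VAF 1.
    """
    vaf = float(vaf)
    if not 0 <= vaf <= 1:
        raise ValidationError(f"vaf must be in [0, 1], got {vaf}")
    if vaf == 0:
        return 0.0
    return 2.0 / (1.0 + 1.0 / vaf)


def ct_fraction_from_het_loss(major_allele_freq: float) -> float:
    """ctDNA fraction from heterozygous-SNP imbalance under one-copy loss.

    With the minor allele lost in tumor, the retained allele's frequency is
    f = 1 / (2 - t), inverted to t = 2 - 1/f and clipped to [0, 1].
    """
    f = float(major_allele_freq)
    if not 0.5 <= f < 1:
        raise ValidationError(
            f"major allele frequency must be in [0.5, 1), got {f}")
    return float(np.clip(2.0 - 1.0 / f, 0.0, 1.0))


@dataclass
class CtEstimate:
    """Per-sample circulating-tumor-fraction estimate."""

    sample_id: str
    ct_fraction: float | None
    method: str                 # vaf_formula | het_loss_snp | none
    surrogate: pd.Series | None = None

    def as_row(self) -> dict:
        return {"sample_id": self.sample_id,
                "ct_fraction": (np.nan if self.ct_fraction is None
                                else self.ct_fraction),
                "method": self.method,
                "surrogate_gene": (None if self.surrogate is None
                                   else self.surrogate.get("gene"))}


def estimate_ct(variants: pd.DataFrame, sample_id: str = "",
                het_loss_major_freq: float | None = None,
                prefiltered: bool = False) -> CtEstimate:
    """Estimate a sample's ctDNA fraction from its variant table.

    Route 1: surrogate somatic VAF through the LOH formula.  Route 2 (no
    passing somatic variant): heterozygous-loss SNP imbalance if a major
    allele frequency is supplied.  Otherwise the method is ``none`` and the
    fraction missing.
    """
    passing = variants if prefiltered else filter_somatic(variants)
    surrogate = select_surrogate(passing) if len(passing) else None
    if surrogate is not None:
        return CtEstimate(sample_id, ct_fraction_from_vaf(surrogate["vaf"]),
                          "vaf_formula", surrogate)
    if het_loss_major_freq is not None:
        return CtEstimate(sample_id,
                          ct_fraction_from_het_loss(het_loss_major_freq),
                          "het_loss_snp")
    return CtEstimate(sample_id, None, "none")
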