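"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are stored 0-based half-open (BED convention)
internally.  Inputs in 1-based inclusive dialects are converted at this
boundary so that no downstream code ever has to reason about conventions.

Readers validate and reject malformed input rather than coercing silently;
every writer emits a file its paired reader parses back to an equal object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "unique_read_support", "vaf",
    "mapq_mean", "background_error", "germline_vaf", "leukocyte_depth",
    "gene", "copy_log_ratio", "consequence", "population_freq",
]


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def tss(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware transcription start positions (0-based)."""
    return pd.Series(
        np.where(genes["strand"].to_numpy() == "+",
                 genes["start"].to_numpy(),
                 genes["end"].to_numpy() - 1),
        index=genes.index, name="tss",
    )


def read_gene_model(path, one_based: bool = False) -> pd.DataFrame:
    """Load a TSV gene model into a validated table.

    Parameters
    ----------
    path : str or Path
        TSV with at least columns ``gene_id, chrom, start, end, strand``.
        ``biotype`` is optional and defaults to ``protein_coding``.
    one_based : bool
        If True the input uses 1-based inclusive coordinates (GTF dialect);
        starts are shifted down by one on load.

    Returns
    -------
    pandas.DataFrame
        Indexed by position, with a ``length`` column (``end - start``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, GENE_MODEL_COLUMNS, f"gene model {path}")
    df = df.copy()
    if one_based:
        df["start"] = df["start"] - 1
    return validate_gene_model(df)


def validate_gene_model(df: pd.DataFrame) -> pd.DataFrame:
    """Check contract of an in-memory gene model and add derived columns."""
    _require_columns(df, GENE_MODEL_COLUMNS, "gene model")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene_id(s): {sorted(set(dup))}")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        raise ValidationError(f"start >= end at row(s) {list(bad[:5])}")
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise ValidationError(f"strand must be +/-, got {sorted(bad_strand)}")
    df = df.reset_index(drop=True)
    if "biotype" not in df.columns:
        df["biotype"] = "protein_coding"
    df["length"] = df["end"] - df["start"]
    return df


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample TSV matrix (first column gene_id, header samples).

    Missing cells written as ``NA`` load as NaN; any other non-numeric cell
    raises :class:`FormatError` naming its coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=True)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"matrix {path} is empty")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise FormatError(
                f"matrix {path}: non-numeric cell at gene {bad[0]!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_peaks(path) -> pd.DataFrame:
    """Read BED3/BED6 peaks; returns chrom/start/end (+ name/score if present),
    sorted by (chrom, start)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"peaks {path}: BED needs >=3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"peaks {path}: start >= end")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_variant_table(path) -> pd.DataFrame:
    """Read a TSV variant table with the panel's filter columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_variant_table(df)


def validate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, VARIANT_COLUMNS, "variant table")
    if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
        raise ValidationError("vaf outside [0, 1]")
    for col in ("unique_read_support", "leukocyte_depth"):
        if (df[col] < 0).any():
            raise ValidationError(f"negative counts in {col}")
    return df.reset_index(drop=True)


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <TAB> description <TAB> genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT {path} line {lineno}: fewer than 3 fields")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path}: expected a YAML mapping")
    return cfg


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
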