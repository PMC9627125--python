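"""Per-gene quantification of 5hmC enrichment sequencing and companion layers.

Turns aligned-fragment intervals plus a gene model into the matrices the
downstream analyses consume: gene-body counts and TPM, promoter CpG
methylation, length-weighted gene copy number, and peak-to-region
annotation frequencies.  Counting covers the entire gene body (gene start
to gene end) and a fragment overlapping several gene bodies increments all
of them ("multioverlap"), matching featureCounts-style gene-body counting
of enrichment data.  Promoters are the window -2000/+500 bp around the
strand-aware transcription start site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import tss as _tss

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500
DOWNSTREAM_WINDOW = 3000

ANNOTATION_CATEGORIES = ["promoter", "exon", "intron", "downstream", "intergenic"]


@dataclass
class OmicsBundle:
    """Aligned gene x sample matrices plus per-sample metadata.

    All matrices share the same gene index and sample columns; ``sample_meta``
    is indexed by sample.  Matrices that a given analysis does not need may be
    ``None``.
    """

    tpm_5hmc: pd.DataFrame
    expr: pd.DataFrame | None = None
    promoter_meth: pd.DataFrame | None = None
    copy_number: pd.DataFrame | None = None
    snv_count: pd.DataFrame | None = None
    sv_count: pd.DataFrame | None = None
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def matrices(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name in ("tpm_5hmc", "expr", "promoter_meth", "copy_number",
                     "snv_count", "sv_count"):
            m = getattr(self, name)
            if m is not None:
                out[name] = m
        return out

    def validate(self) -> "OmicsBundle":
        mats = self.matrices()
        ref = self.tpm_5hmc
        for name, m in mats.items():
            if not m.index.equals(ref.index) or not m.columns.equals(ref.columns):
                raise ValidationError(f"matrix {name} not aligned with tpm_5hmc")
        if len(self.sample_meta) and not self.sample_meta.index.equals(
                pd.Index(ref.columns)):
            raise ValidationError("sample_meta index does not match sample columns")
        return self


def _genes_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for i, s, e in zip(sub.index, sub["start"], sub["end"]):
            t.addi(int(s), int(e), i)
        trees[chrom] = t
    return trees


def gene_body_counts(fragments: dict[str, pd.DataFrame] | pd.DataFrame,
                     genes: pd.DataFrame,
                     multioverlap: bool = True) -> pd.DataFrame:
    """Count fragments over gene bodies, one column per sample.

    A fragment overlaps a gene if their intervals intersect in >= 1 bp on the
    half-open convention.  With ``multioverlap`` (the default) a fragment
    overlapping k gene bodies increments all k counts; otherwise only
    fragments overlapping exactly one gene are counted.

    ``fragments`` is either a mapping sample_id -> BED-like frame
    (chrom/start/end) or a single frame with a ``sample_id`` column.
    """
    if isinstance(fragments, pd.DataFrame):
        if "sample_id" not in fragments.columns:
            raise ValidationError("fragment frame needs a sample_id column")
        fragments = {s: sub for s, sub in fragments.groupby("sample_id")}
    trees = _genes_trees(genes)
    gene_chroms = set(trees)
    counts = pd.DataFrame(0, index=genes["gene_id"].to_numpy(),
                          columns=list(fragments), dtype=int)
    gene_ids = genes["gene_id"].to_numpy()
    for sample, frame in fragments.items():
        frag_chroms = set(frame["chrom"])
        if frag_chroms and not (frag_chroms & gene_chroms):
            raise ValidationError(
                f"sample {sample}: no chromosome names shared with gene model")
        col = counts[sample].to_numpy()
        for chrom, start, end in zip(frame["chrom"], frame["start"], frame["end"]):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = tree.overlap(int(start), int(end))
            if not multioverlap and len(hits) != 1:
                continue
            for h in hits:
                col[h.data] += 1
        counts[sample] = col
    counts.index.name = "gene_id"
    return counts


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Normalize counts for gene length and depth to transcripts per million.

    Per sample, ``rate_g = counts_g / (length_g / 1000)`` and
    ``TPM_g = rate_g / sum(rate) * 1e6`` so every column sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive for all counted genes")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero count column(s): {list(zero)}")
    return rate.div(totals, axis=1) * 1e6


def promoter_region(start: int, end: int, strand: str) -> tuple[int, int]:
    """Promoter window -2000/+500 bp around the strand-aware TSS, clamped at 0.

    Plus strand (TSS = start): ``[TSS-2000, TSS+500)``; minus strand
    (TSS = end): ``[TSS-500, TSS+2000)``.
    """
    if strand == "+":
        lo, hi = start - PROMOTER_UPSTREAM, start + PROMOTER_DOWNSTREAM
    elif strand == "-":
        lo, hi = end - PROMOTER_DOWNSTREAM, end + PROMOTER_UPSTREAM
    else:
        raise ValidationError(f"strand must be +/-, got {strand!r}")
    return max(0, lo), hi


def promoter_regions(genes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized promoter windows for a whole gene model."""
    plus = genes["strand"].to_numpy() == "+"
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    lo = np.where(plus, start - PROMOTER_UPSTREAM, end - PROMOTER_DOWNSTREAM)
    hi = np.where(plus, start + PROMOTER_DOWNSTREAM, end + PROMOTER_UPSTREAM)
    return pd.DataFrame({"gene_id": genes["gene_id"], "chrom": genes["chrom"],
                         "start": np.maximum(0, lo), "end": hi})


def promoter_methylation(cpg: dict[str, pd.DataFrame],
                         genes: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean CpG methylation in each gene's promoter window.

    ``cpg`` maps sample -> table with columns chrom/pos/meth (fractions in
    [0, 1]).  Genes with no CpG in the window are missing (NaN).
    """
    proms = promoter_regions(genes)
    out = pd.DataFrame(np.nan, index=genes["gene_id"].to_numpy(), columns=list(cpg))
    for sample, table in cpg.items():
        if ((table["meth"] < 0) | (table["meth"] > 1)).any():
            raise ValidationError(f"sample {sample}: methylation outside [0, 1]")
        by_chrom = {c: sub.sort_values("pos") for c, sub in table.groupby("chrom")}
        vals = np.full(len(proms), np.nan)
        for i, (chrom, lo, hi) in enumerate(zip(proms["chrom"], proms["start"],
                                                proms["end"])):
            sub = by_chrom.get(chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            a, b = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            if b > a:
                vals[i] = sub["meth"].to_numpy()[a:b].mean()
        out[sample] = vals
    out.index.name = "gene_id"
    return out


def gene_copy_number(segments: dict[str, pd.DataFrame],
                     genes: pd.DataFrame) -> pd.DataFrame:
    """Length-weighted mean segment copy number over each gene body.

    ``segments`` maps sample -> table chrom/start/end/cn with non-overlapping
    segments per sample; genes with no covered base are missing.
    """
    out = pd.DataFrame(np.nan, index=genes["gene_id"].to_numpy(),
                       columns=list(segments))
    for sample, table in segments.items():
        for chrom, sub in table.groupby("chrom"):
            sub = sub.sort_values("start")
            if (sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]).any():
                raise ValidationError(
                    f"sample {sample}: overlapping segments on {chrom}")
        vals = np.full(len(genes), np.nan)
        by_chrom = {c: sub.sort_values("start") for c, sub in table.groupby("chrom")}
        for i, (chrom, gs, ge) in enumerate(zip(genes["chrom"], genes["start"],
                                                genes["end"])):
            sub = by_chrom.get(chrom)
            if sub is None:
                continue
            ov_lo = np.maximum(sub["start"].to_numpy(), gs)
            ov_hi = np.minimum(sub["end"].to_numpy(), ge)
            w = np.clip(ov_hi - ov_lo, 0, None).astype(float)
            if w.sum() > 0:
                vals[i] = float(np.average(sub["cn"].to_numpy(), weights=w))
        out[sample] = vals
    out.index.name = "gene_id"
    return out


def _exon_intervals(row) -> list[tuple[int, int]]:
    if "block_starts" in row and isinstance(row["block_starts"], str) \
            and row["block_starts"]:
        starts = [int(x) for x in str(row["block_starts"]).split(",") if x != ""]
        sizes = [int(x) for x in str(row["block_sizes"]).split(",") if x != ""]
        return [(row["start"] + s, row["start"] + s + z)
                for s, z in zip(starts, sizes)]
    return [(row["start"], row["end"])]  # single-exon fallback


def annotate_peaks(peaks: pd.DataFrame,
                   genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each peak one genomic category and the closest gene by TSS.

    The peak midpoint decides membership; categories are resolved by the fixed
    precedence promoter > exon > intron > downstream > intergenic across all
    genes.  "Downstream" is the 3 kb window strand-aware past the gene end.
    Returns the annotated per-peak frame and category frequencies (sum 1).
    """
    proms = promoter_regions(genes)
    prom_trees: dict[str, IntervalTree] = {}
    for chrom, sub in proms.groupby("chrom"):
        t = IntervalTree()
        for lo, hi in zip(sub["start"], sub["end"]):
            t.addi(int(lo), int(hi))
        prom_trees[chrom] = t
    exon_trees: dict[str, IntervalTree] = {}
    body_trees = _genes_trees(genes)
    down_trees: dict[str, IntervalTree] = {}
    for _, row in genes.iterrows():
        et = exon_trees.setdefault(row["chrom"], IntervalTree())
        for lo, hi in _exon_intervals(row):
            if hi > lo:
                et.addi(int(lo), int(hi))
        dt = down_trees.setdefault(row["chrom"], IntervalTree())
        if row["strand"] == "+":
            dt.addi(int(row["end"]), int(row["end"]) + DOWNSTREAM_WINDOW)
        else:
            lo = max(0, int(row["start"]) - DOWNSTREAM_WINDOW)
            if row["start"] > lo:
                dt.addi(lo, int(row["start"]))

    gene_tss = _tss(genes).to_numpy()
    tss_by_chrom = {c: np.sort(gene_tss[genes["chrom"].to_numpy() == c])
                    for c in genes["chrom"].unique()}
    tss_ids = {}
    for c in genes["chrom"].unique():
        mask = genes["chrom"].to_numpy() == c
        order = np.argsort(gene_tss[mask])
        tss_ids[c] = genes["gene_id"].to_numpy()[mask][order]

    cats, closest = [], []
    for chrom, start, end in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        mid = (int(start) + int(end)) // 2
        if chrom in prom_trees and prom_trees[chrom].overlaps_point(mid):
            cat = "promoter"
        elif chrom in exon_trees and exon_trees[chrom].overlaps_point(mid):
            cat = "exon"
        elif chrom in body_trees and body_trees[chrom].overlaps_point(mid):
            cat = "intron"
        elif chrom in down_trees and down_trees[chrom].overlaps_point(mid):
            cat = "downstream"
        else:
            cat = "intergenic"
        cats.append(cat)
        pos_arr = tss_by_chrom.get(chrom)
        if pos_arr is None or len(pos_arr) == 0:
            closest.append(None)
        else:
            j = np.searchsorted(pos_arr, mid)
            cands = [k for k in (j - 1, j) if 0 <= k < len(pos_arr)]
            best = min(cands, key=lambda k: abs(pos_arr[k] - mid))
            closest.append(tss_ids[chrom][best])
    annotated = peaks.copy()
    annotated["category"] = pd.Categorical(cats, categories=ANNOTATION_CATEGORIES)
    annotated["closest_gene"] = closest
    freqs = annotated["category"].value_counts(normalize=True).reindex(
        ANNOTATION_CATEGORIES, fill_value=0.0)
    return annotated, freqs


def top_variable_genes(matrix: pd.DataFrame, fraction: float = 0.10) -> list[str]:
    """Genes in the top `fraction` by across-sample variance.

    Intended for log2(TPM+1) input.  Zero-variance genes are excluded from the
    ranking; ties break by gene_id lexicographic order.  Returns
    ``ceil(fraction * n_genes)`` gene ids (fewer if not enough vary).
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    var = matrix.var(axis=1, ddof=1)
    var = var[var > 0]
    k = math.ceil(fraction * matrix.shape[0])
    ranked = var.rename_axis("gene_id").to_frame("var").reset_index()
    ranked = ranked.sort_values(["var", "gene_id"], ascending=[False, True])
    return ranked["gene_id"].head(k).tolist()


def median_center_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-center and scale each gene (row); zero-variance rows become NaN."""
    med = matrix.median(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    out = matrix.sub(med, axis=0).div(sd.where(sd > 0), axis=0)
    return out


def pca_embed(matrix: pd.DataFrame, n_components: int | None = None):
    """PCA of samples on a genes x samples matrix (already selected & scaled).

    Returns (coordinates: samples x PCs, explained_variance ratios), components
    ordered by decreasing variance (SVD).
    """
    X = matrix.to_numpy(dtype=float).T
    n_components = n_components or min(X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=matrix.columns, columns=cols),
            pca.explained_variance_ratio_)


def hier_cluster(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Ward (ward.D2-style) hierarchical clustering of samples, cut at k groups.

    Distances are Euclidean over the gene dimension; input should already be
    top-variable-selected and median-centered/scaled.
    """
    n = matrix.shape[1]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of samples ({n})")
    Z = linkage(matrix.to_numpy(dtype=float).T, method="ward",
                metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster")
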