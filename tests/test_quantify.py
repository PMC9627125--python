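"""Quantification oracles: counting, TPM, promoters, copy number, annotation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hmcseq import quantify
from hmcseq.errors import ValidationError


def _brute_force_counts(frags, genes):
    """Quadratic all-pairs overlap scan (independent oracle)."""
    out = {g: 0 for g in genes["gene_id"]}
    for _, f in frags.iterrows():
        for _, g in genes.iterrows():
            if f["chrom"] == g["chrom"] and f["start"] < g["end"] \
                    and g["start"] < f["end"]:
                out[g["gene_id"]] += 1
    return pd.Series(out)


class TestGeneBodyCounts:
    def test_fragment_inside_single_gene(self, toy_genes):
        frags = {"s1": pd.DataFrame({"chrom": ["chr2"], "start": [3000],
                                     "end": [3100]})}
        counts = quantify.gene_body_counts(frags, toy_genes)
        assert counts["s1"].tolist() == [0, 0, 1]

    def test_fragment_spanning_overlapping_genes_counts_both(self, toy_genes):
        # GA [1000,5000) and GB [4000,9000) overlap; a fragment across the
        # junction increments both under multioverlap
        frags = {"s1": pd.DataFrame({"chrom": ["chr1"], "start": [4400],
                                     "end": [4600]})}
        counts = quantify.gene_body_counts(frags, toy_genes, multioverlap=True)
        assert counts["s1"].tolist() == [1, 1, 0]
        strict = quantify.gene_body_counts(frags, toy_genes, multioverlap=False)
        assert strict["s1"].tolist() == [0, 0, 0]

    def test_matches_brute_force_oracle_on_random_fragments(self, toy_genes,
                                                            rng):
        frags = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 100),
            "start": rng.integers(0, 12000, 100),
        })
        frags["end"] = frags["start"] + rng.integers(50, 500, 100)
        counts = quantify.gene_body_counts({"s": frags}, toy_genes)
        expected = _brute_force_counts(frags, toy_genes)
        assert (counts["s"] == expected.reindex(counts.index)).all()

    def test_disjoint_chromosomes_error(self, toy_genes):
        frags = {"s1": pd.DataFrame({"chrom": ["chr9"], "start": [0],
                                     "end": [10]})}
        with pytest.raises(ValidationError, match="chromosome"):
            quantify.gene_body_counts(frags, toy_genes)


class TestTpm:
    def test_equal_rates_split_evenly(self):
        counts = pd.DataFrame({"s": [10, 20]}, index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        tpm = quantify.tpm_normalize(counts, lengths)
        assert np.allclose(tpm["s"], [500_000, 500_000])

    def test_single_gene_gets_everything(self):
        counts = pd.DataFrame({"s": [7]}, index=["a"])
        tpm = quantify.tpm_normalize(counts, pd.Series([1234], index=["a"]))
        assert tpm.loc["a", "s"] == pytest.approx(1e6)

    def test_columns_conserve_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 5)),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(5)])
        counts.iloc[0] += 1  # guard against an all-zero column
        lengths = pd.Series(rng.integers(500, 50000, 50), index=counts.index)
        tpm = quantify.tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_is_named_in_error(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]}, index=["a"])
        with pytest.raises(ValidationError, match="empty"):
            quantify.tpm_normalize(counts, pd.Series([1000], index=["a"]))


class TestPromoters:
    def test_plus_strand_window(self):
        assert quantify.promoter_region(10_000, 20_000, "+") == (8000, 10_500)

    def test_minus_strand_window_mirrors(self):
        assert quantify.promoter_region(2_000, 10_000, "-") == (9_500, 12_000)

    def test_clamped_at_origin(self):
        assert quantify.promoter_region(1_000, 5_000, "+") == (0, 1_500)

    def test_strand_reflection_symmetry(self, rng):
        """Reflecting coordinates and flipping strand maps windows exactly."""
        L = 1_000_000
        for _ in range(50):
            s = int(rng.integers(10_000, 900_000))
            e = s + int(rng.integers(1_000, 50_000))
            lo_p, hi_p = quantify.promoter_region(s, e, "+")
            lo_m, hi_m = quantify.promoter_region(L - e, L - s, "-")
            assert (lo_m, hi_m) == (L - hi_p, L - lo_p)

    def test_methylation_mean_and_missing(self, toy_genes):
        # GA is + with TSS 1000 -> window [0, 1500); GB is - with window
        # [8500, 11000) which holds no CpG here -> missing
        cpg = {"s1": pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                                   "pos": [500, 1200, 100],
                                   "meth": [0.2, 0.8, 0.5]})}
        pm = quantify.promoter_methylation(cpg, toy_genes)
        assert pm.loc["GA", "s1"] == pytest.approx(0.5)
        assert np.isnan(pm.loc["GB", "s1"])

    def test_methylation_matches_brute_force(self, toy_genes, rng):
        pos = np.sort(rng.integers(0, 12_000, 20))
        meth = rng.random(20)
        cpg = {"s": pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": meth})}
        pm = quantify.promoter_methylation(cpg, toy_genes)
        proms = quantify.promoter_regions(toy_genes).set_index("gene_id")
        for gid in ["GA", "GB"]:
            lo, hi = proms.loc[gid, ["start", "end"]]
            mask = (pos >= lo) & (pos < hi)
            expected = meth[mask].mean() if mask.any() else np.nan
            got = pm.loc[gid, "s"]
            assert (np.isnan(got) and np.isnan(expected)) \
                or got == pytest.approx(expected)


class TestCopyNumber:
    def test_gene_in_single_segment(self, toy_genes):
        segs = {"s": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                   "end": [20_000], "cn": [3.0]})}
        cn = quantify.gene_copy_number(segs, toy_genes)
        assert cn.loc["GA", "s"] == pytest.approx(3.0)
        assert np.isnan(cn.loc["GC", "s"])

    def test_half_and_half_weighted_mean(self):
        genes = pd.DataFrame({"gene_id": ["G"], "chrom": ["chr1"],
                              "start": [1000], "end": [3000], "strand": ["+"]})
        segs = {"s": pd.DataFrame({"chrom": ["chr1", "chr1"],
                                   "start": [0, 2000], "end": [2000, 5000],
                                   "cn": [2.0, 4.0]})}
        cn = quantify.gene_copy_number(segs, genes)
        assert cn.loc["G", "s"] == pytest.approx(3.0)

    def test_matches_per_bp_brute_force(self, rng):
        genes = pd.DataFrame({"gene_id": ["G"], "chrom": ["chr1"],
                              "start": [100], "end": [900], "strand": ["+"]})
        cuts = np.sort(rng.choice(np.arange(1, 1000), 5, replace=False))
        bounds = [0, *cuts, 1000]
        vals = rng.uniform(1, 5, len(bounds) - 1)
        segs = pd.DataFrame({"chrom": "chr1", "start": bounds[:-1],
                             "end": bounds[1:], "cn": vals})
        cn = quantify.gene_copy_number({"s": segs}, genes)
        per_bp = np.empty(1000)
        for lo, hi, v in zip(segs["start"], segs["end"], segs["cn"]):
            per_bp[lo:hi] = v
        assert cn.loc["G", "s"] == pytest.approx(per_bp[100:900].mean(),
                                                 abs=1e-9)

    def test_overlapping_segments_rejected(self, toy_genes):
        segs = {"s": pd.DataFrame({"chrom": ["chr1", "chr1"],
                                   "start": [0, 500], "end": [1000, 1500],
                                   "cn": [2, 3]})}
        with pytest.raises(ValidationError, match="overlap"):
            quantify.gene_copy_number(segs, toy_genes)


class TestAnnotatePeaks:
    def test_promoter_takes_precedence_over_exon(self):
        # promoter of gene B [TSS-2000, TSS+500) overlaps an exon of gene A
        genes = pd.DataFrame({
            "gene_id": ["A", "B"], "chrom": ["chr1", "chr1"],
            "start": [1000, 6000], "end": [5000, 9000],
            "strand": ["+", "+"],
            "block_starts": ["0,3000", "0"], "block_sizes": ["500,1000", "3000"],
        })
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [4100],
                              "end": [4300]})  # midpoint 4200: A exon + B promoter
        annotated, freqs = quantify.annotate_peaks(peaks, genes)
        assert annotated.loc[0, "category"] == "promoter"
        assert freqs.sum() == pytest.approx(1.0)

    def test_empty_chromosome_is_intergenic(self, toy_genes):
        peaks = pd.DataFrame({"chrom": ["chr7"], "start": [100], "end": [200]})
        annotated, _ = quantify.annotate_peaks(peaks, toy_genes)
        assert annotated.loc[0, "category"] == "intergenic"

    def test_category_frequencies_partition(self, toy_genes, rng):
        peaks = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2", "chr3"], 60),
                              "start": rng.integers(0, 15_000, 60)})
        peaks["end"] = peaks["start"] + 200
        annotated, freqs = quantify.annotate_peaks(peaks, toy_genes)
        assert not annotated["category"].isna().any()
        assert freqs.sum() == pytest.approx(1.0)

    def test_closest_gene_by_tss(self, toy_genes):
        # GA TSS=1000 (+), GB TSS=8999 (-)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1400],
                              "end": [1600]})
        annotated, _ = quantify.annotate_peaks(peaks, toy_genes)
        assert annotated.loc[0, "closest_gene"] == "GA"


class TestVariableGenesAndScaling:
    def test_top_fraction_selects_largest_variance(self, rng):
        X = pd.DataFrame(rng.normal(0, 0.1, (20, 30)),
                         index=[f"g{i:02d}" for i in range(20)])
        X.iloc[3] += rng.normal(0, 5, 30)
        X.iloc[17] += rng.normal(0, 3, 30)
        top = quantify.top_variable_genes(X, fraction=0.10)
        assert set(top) == {"g03", "g17"}

    def test_constant_gene_excluded(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]], index=["const", "var"])
        top = quantify.top_variable_genes(X, fraction=1.0)
        assert top == ["var"]

    def test_scaled_rows_have_zero_median(self, rng):
        X = pd.DataFrame(rng.normal(2, 3, (10, 31)))
        scaled = quantify.median_center_scale(X)
        assert np.allclose(scaled.median(axis=1), 0.0, atol=1e-12)

    def test_zero_variance_row_becomes_missing(self):
        X = pd.DataFrame([[2.0, 2.0, 2.0]], index=["const"])
        scaled = quantify.median_center_scale(X)
        assert scaled.isna().all().all()


class TestEmbeddingAndClustering:
    @pytest.fixture()
    def two_groups(self, rng):
        a = rng.normal(0, 1, (40, 10)) + 6
        b = rng.normal(0, 1, (40, 10)) - 6
        X = pd.DataFrame(np.hstack([a, b]),
                         columns=[f"s{i}" for i in range(20)])
        labels = np.array([0] * 10 + [1] * 10)
        return X, labels

    def test_pc1_separates_planted_groups(self, two_groups):
        X, labels = two_groups
        coords, ratios = quantify.pca_embed(X)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[labels == 0].mean() > 0) != (pc1[labels == 1].mean() > 0)
        assert abs(pc1[labels == 0].mean() - pc1[labels == 1].mean()) > 10
        assert np.all(np.diff(ratios) <= 1e-12)  # non-increasing variances

    def test_ward_clustering_recovers_partition(self, two_groups):
        X, labels = two_groups
        got = quantify.hier_cluster(X, k=2)
        assert adjusted_rand_score(labels, got.to_numpy()) == 1.0

    def test_duplicate_samples_merge_first(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]})
        got = quantify.hier_cluster(X, k=2)
        assert got["a"] == got["b"] != got["c"]

    def test_k_larger_than_samples_rejected(self, two_groups):
        X, _ = two_groups
        with pytest.raises(ValidationError):
            quantify.hier_cluster(X, k=21)
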