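import numpy as np
import pandas as pd
import pytest

from hmcseq import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = synth.CohortConfig(n_genes=120, n_samples=60, seed=11)
    genes, bundle, truth = synth.generate_cohort(cfg)
    return cfg, genes, bundle, truth


@pytest.fixture(scope="session")
def tissue_panel():
    return synth.generate_tissue_panel(n_genes=300, seed=3)


@pytest.fixture()
def toy_genes():
    """Three genes on two chromosomes, one pair overlapping, mixed strands."""
    return pd.DataFrame({
        "gene_id": ["GA", "GB", "GC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1000, 4000, 2000],
        "end": [5000, 9000, 6000],
        "strand": ["+", "-", "+"],
        "biotype": "protein_coding",
        "length": [4000, 5000, 4000],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
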