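import numpy as np
import pandas as pd
import pytest

import stratwas as sw


@pytest.fixture(scope="session")
def small_config():
    return sw.SimConfig(
        n_samples_per_stratum=120,
        n_genes=4,
        n_variants_per_gene_cis=12,
        n_trans_variants=4,
        cis_h2_per_gene=0.35,
        n_causal_cis=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sw.simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, positions=None, chrom="chr1", samples=None,
                   ids=None, ref="A", alt="G"):
    """Build a GenotypeMatrix from a raw dosage array for toy tests."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if ids is None:
        ids = [f"v{j}" for j in range(m)]
    variants = pd.DataFrame({
        "id": ids, "chrom": chrom, "pos": positions, "ref": ref, "alt": alt,
    })
    return sw.GenotypeMatrix(dosages, variants, samples)


def make_expression(values, genes=None, samples=None):
    values = np.asarray(values, float)
    n, g = values.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if genes is None:
        genes = pd.DataFrame({
            "id": [f"gene{j}" for j in range(g)],
            "chrom": "chr1",
            "start": np.arange(g) * 2_000_000 + 1_000_000,
            "end": np.arange(g) * 2_000_000 + 1_010_000,
        })
    return sw.ExpressionMatrix(values, genes, samples)
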