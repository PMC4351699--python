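import numpy as np
import pandas as pd
import pytest

from coloneqtl.datatypes import GeneAnnotation, GenotypeTable
from coloneqtl.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest planted-effect cohort reused by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=80,
        n_snps=400,
        n_genes=40,
        n_planted_cis=15,
        effect_size_r2=0.3,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_genotypes(dosage_matrix, positions=None, chrom="1", sample_prefix="S"):
    """GenotypeTable from a raw (samples x snps) array, for hand fixtures."""
    mat = np.asarray(dosage_matrix, dtype=float)
    n, m = mat.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    snp_ids = [f"s{j}" for j in range(m)]
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, np.int64), "ref": "A", "alt": "G"},
        index=snp_ids,
    )
    dosages = pd.DataFrame(
        mat, index=[f"{sample_prefix}{i}" for i in range(n)], columns=snp_ids
    )
    return GenotypeTable(dosages, snps)


def make_annotation(rows):
    """GeneAnnotation from (probe_id, gene_id, chrom, strand, tss, tes) tuples."""
    table = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "chrom", "strand", "tss", "tes"]
    ).set_index("probe_id")
    table["multi_mapped"] = False
    table["contains_common_snp"] = False
    return GeneAnnotation(table)
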