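import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from superbiv.chip_quant import promoter_enrichment_matrix
from superbiv.synthetic_data import (
    SimulationConfig,
    simulate_chip_reads,
    simulate_genome_and_genes,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A reduced dataset (fast) that keeps the default statistical structure.

    Depths are unchanged so RPKM magnitudes and thresholds behave as at full
    scale; only the gene count and genome length shrink.
    """
    return SimulationConfig(
        seed=7,
        n_genes_per_class={"housekeeping": 10, "bivalent": 12, "super_bivalent": 6,
                           "active": 8, "silent": 8},
        chrom_length=2_500_000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genome, genes, truth = simulate_genome_and_genes(small_config)
    k4 = simulate_chip_reads(genes, truth, small_config, "H3K4me3", sample_id="s1")
    k27 = simulate_chip_reads(genes, truth, small_config, "H3K27me3", sample_id="s1")
    return {"config": small_config, "genome": genome, "genes": genes,
            "truth": truth, "k4": k4, "k27": k27}


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    d = small_dataset
    out = {}
    for mark, reads in (("H3K4me3", d["k4"]), ("H3K27me3", d["k27"])):
        for bp, tag in ((10_000, "10kb"), (5_000, "5kb")):
            out[f"{mark}_{tag}"] = promoter_enrichment_matrix(
                d["genes"], {"s1": reads}, mark, d["genome"], bp
            )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
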