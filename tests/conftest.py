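import numpy as np
import pandas as pd
import pytest

from promdyn.synthetic import (
    GenomeModel,
    SimulationParams,
    default_mark_folds,
    gen_chip_reads,
    gen_genome,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """50 genes on one 1 Mb chromosome, mixed classes."""
    return gen_genome(1, 1_000_000, 50, (0.3, 0.5, 0.2), seed=11)


@pytest.fixture(scope="session")
def enriched_readsets(small_genome):
    """IP/input pair with 20-fold H3K4me3 signal at bivalent+active TSSs."""
    params = SimulationParams(
        total_reads=400_000,
        fold_by_class=default_mark_folds("H3K4me3", 20.0),
        seed=3,
    )
    return gen_chip_reads(small_genome, params, "H3K4me3")


@pytest.fixture()
def tiny_genes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1"] * 3,
            "tss": [10_000, 50_000, 90_000],
            "strand": ["+", "-", "+"],
        }
    )
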