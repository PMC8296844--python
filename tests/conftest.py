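import numpy as np
import pytest
from hypothesis import settings

from plastevo.synthetic import SimConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """8 taxa x 6 genes with one planted lesion of each kind."""
    cfg = SimConfig(
        seed=11, n_taxa=8, n_genes=6, gene_length_codons=(60, 90),
        lesion_plan=[
            ("atpA", "t02", "premature_stop", 0.4),
            ("petA", "t03", "frameshift", 0.5),
            ("ndhA", "t04", "truncation", 0.5),
            ("psaA", "t05", "deletion", 0.3),
        ],
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
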