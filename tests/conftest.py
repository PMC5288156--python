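import numpy as np
import pytest

from concordkit.synthetic import TruthConfig


@pytest.fixture
def small_config():
    """Desk-scale tumor: copy-neutral genome, moderate burden."""
    return TruthConfig(
        purity=0.76,
        n_clonal_mutations=200,
        mean_depth_center_A=200,
        mean_depth_center_B=150,
        targets_per_chromosome=300,
        expression_n_genes=500,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
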