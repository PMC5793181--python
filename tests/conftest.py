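import numpy as np
import pytest

from srnascape.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_design(n_per_subtype: int = 3):
    return tuple(
        (f"{st}_{i + 1}", st)
        for st in ("BL1", "BL2", "M", "LAR")
        for i in range(n_per_subtype)
    )


@pytest.fixture
def small_sim_config():
    """A fast, fully featured simulation: 12 samples, 3,000 reads each."""
    return SimulationConfig(
        seed=11,
        reads_per_sample=3_000,
        design=small_design(3),
        features_per_category={
            "miRNA": 20, "tRNA": 8, "snoRNA": 5, "snRNA": 4,
            "yRNA": 3, "7SK": 2, "7SL": 2,
        },
        spike_table=[
            ("miRNA_0001", "LAR", 3.0),
            ("miRNA_0002", "LAR", 3.0),
            ("miRNA_0003", "M", 3.0),
        ],
    )
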