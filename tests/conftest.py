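import warnings

import numpy as np
import pandas as pd
import pytest

from screenbias.datamodel import GenomeAnnotation
from screenbias.synthetic import SimConfig, simulate_bundle, tiny_config

# arm-assignment warnings for deliberately unmapped genes are routine in tests
warnings.filterwarnings("ignore", message=".*without arm assignment.*")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small biased bundle (4 chromosomes, 200 genes, 12 models)."""
    return simulate_bundle(tiny_config(seed=123))


@pytest.fixture(scope="session")
def default_bundle():
    """Default study conditions: CN bias + TP53-dependent arm offsets."""
    return simulate_bundle(SimConfig(seed=42))


@pytest.fixture(scope="session")
def unbiased_bundle():
    """Same layout with all structural biases switched off."""
    return simulate_bundle(
        SimConfig(seed=42, arm_offset_sd_wt=0.0, arm_offset_sd_mut=0.0, cn_bias_slope=0.0)
    )


@pytest.fixture(scope="session")
def counts_bundle():
    """Tiny bundle with negative-binomial read-count emission."""
    return simulate_bundle(tiny_config(seed=7, emit_counts=True))


@pytest.fixture()
def simple_annotation():
    """One chromosome, centromere at 40 Mb, six genes per arm."""
    genes = pd.DataFrame(
        {
            "chromosome": ["1"] * 12,
            "start": list(np.arange(1, 7) * 5_000_000)
            + list(40_000_000 + np.arange(1, 7) * 5_000_000),
        },
        index=[f"P{i}" for i in range(6)] + [f"Q{i}" for i in range(6)],
    )
    return GenomeAnnotation(genes, pd.Series({"1": 40_000_000}))
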