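import numpy as np
import pandas as pd
import pytest

from clonalmix.sagp_inference import SampleBaseline
from clonalmix.simulation import SimulationConfig, simulate_scna_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_baseline():
    """Noise-free baseline at the origin with floor-level scatter."""
    return SampleBaseline(x0=0.0, y0=0.0, sd_baf=1e-4, sd_lrr=1e-4)


@pytest.fixture
def noisy_baseline():
    """Baseline with the segment-level noise scale of the validation study."""
    return SampleBaseline(x0=0.0, y0=0.0, sd_baf=0.01, sd_lrr=0.04)


@pytest.fixture
def simulated_tumor(rng):
    """One simulated tumor segment table (dominant 0.9 / minor 0.4)."""
    cfg = SimulationConfig(p_dom=0.9, p_sub=0.4, seed=7)
    return simulate_scna_dataset(cfg, np.random.default_rng(7))


def make_signals(n=100, chrom="1", het_every=1, baf=0.5, lrr=0.0,
                 start=1000, spacing=1000):
    """Small hand-built site-signal frame for segmentation tests."""
    pos = start + spacing * np.arange(n)
    return pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "baf": np.full(n, baf, dtype=float),
        "lrr": np.full(n, lrr, dtype=float),
        "is_het": (np.arange(n) % het_every == 0),
    })
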