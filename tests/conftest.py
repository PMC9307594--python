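import warnings

import numpy as np
import pytest

from slipfret import PhotophysicsModel, analyze_traces, simulate_preset
from slipfret.config import AnalysisConfig

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def photo():
    return PhotophysicsModel()


@pytest.fixture
def noiseless_photo():
    """Photophysics with no noise, no bleaching, no bleed-through."""
    return PhotophysicsModel(k_pb_donor=0.0, bleedthrough_beta=0.0,
                             noise_sd=0.0, background_sd=1e-9)


@pytest.fixture(scope="session")
def wt_slow_analysis():
    """Analyzed slow-mode wt slippery ensemble shared across kinetics tests."""
    cfg = AnalysisConfig(hmm_mode="fixed", n_boot=0)
    traces, manifest, mixture = simulate_preset(
        "pept_wt_slippery", 120, 2024, component="slow")
    result = analyze_traces(traces, config=cfg, mixture=mixture)
    result["manifest"] = manifest
    return result


def make_rng(seed=0):
    return np.random.default_rng(seed)
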