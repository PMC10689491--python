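import warnings

import numpy as np
import pytest

from vmvar import synth


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*Covariance of the parameters.*")
        yield


@pytest.fixture
def clean_params():
    """Noise-free, oscillation-free, single-downstate generator parameters."""
    return synth.genotype_presets(
        "wt_like",
        fs=10000.0,
        noise_sd=0.0,
        osc_amp={k: 0.0 for k in synth.BAND_CENTERS},
        p_fail=0.0,
        epsp_amp_sd=0.0,
        epsp_latency_jitter=0.0,
        state_gain=0.0,
        spont_ap_rate=0.0,
        dur_down=500.0,
        seed=0,
    )


def two_state_square(fs: float, period_s: float, n_periods: int,
                     v_lo: float = -70.0, v_hi: float = -50.0) -> np.ndarray:
    """Square wave alternating v_lo/v_hi with 50% duty, starting low."""
    half = int(round(period_s * fs / 2))
    cycle = np.concatenate([np.full(half, v_lo), np.full(half, v_hi)])
    return np.tile(cycle, n_periods)
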