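import numpy as np
import pytest

from wktau.pipeline import cohort_with_features
from wktau.population import PopulationConfig
from wktau.windkessel import WindkesselParams, half_sine_flow, solve_wk2_periodic


@pytest.fixture(scope="session")
def default_params() -> WindkesselParams:
    """A resting mid-cohort subject: tau = 1.1 s, MBP = 100 mmHg."""
    return WindkesselParams(R=1.0, C=1.1, T=0.7, ts=0.245, SV=70.0)


@pytest.fixture(scope="session")
def wk_wave(default_params):
    """(flow, pressure) for the default subject at 1 kHz."""
    p = default_params
    flow = half_sine_flow(p.T, p.ts, p.SV, 1000.0)
    return flow, solve_wk2_periodic(p, flow)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject cohort with noiseless waveform features."""
    table, subjects = cohort_with_features(PopulationConfig(n=120, seed=5))
    return table, subjects


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def roll_to_foot():
    """Align a clean cycle to start at its pressure minimum (the detected
    foot), matching the phase convention of ``average_beats`` output."""

    def _roll(samples: np.ndarray) -> np.ndarray:
        return np.roll(samples, -int(np.argmin(samples)))

    return _roll
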