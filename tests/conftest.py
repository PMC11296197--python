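import numpy as np
import pytest

from spongesaxs import CohortConfig, PeakModelParams, ScatteringCurve, model_eval


@pytest.fixture
def example_params() -> PeakModelParams:
    """A typical spongy-layer Porod-space peak model."""
    return PeakModelParams(
        c=2.0, a1=100.0, q1=0.045, h1=0.007, alpha=0.3, beta=5.0 / 3.0, h2=0.012
    )


@pytest.fixture
def q_grid() -> np.ndarray:
    return np.linspace(0.01, 0.25, 400)


@pytest.fixture
def noiseless_curve(example_params, q_grid) -> ScatteringCurve:
    """Scattering curve whose Porod transform is exactly the peak model."""
    intensity = model_eval(example_params, q_grid) / q_grid**4
    return ScatteringCurve(q_grid, intensity, np.zeros_like(q_grid), {"sample": "S0"})


@pytest.fixture
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture
def small_config() -> CohortConfig:
    """Reduced replicate counts for fast per-sample pipeline tests."""
    return CohortConfig(n_males=4, n_females=3, n_positions=5, n_exposures=2)
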