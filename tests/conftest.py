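import numpy as np
import pytest

from tinnpsych.model import FitConfig, PsychometricParams
from tinnpsych.pipeline import simulate_run
from tinnpsych.protocols import design_psychometric_run


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cfg():
    """Study-default fit configuration (45/30 threshold prior, 0-90 dB grid)."""
    return FitConfig(seed=0)


@pytest.fixture(scope="session")
def coarse_cfg():
    """Coarser grids for unit tests that fit many small runs."""
    return FitConfig(
        alpha_lo=20.0, alpha_hi=70.0, alpha_step=0.5,
        n_beta=60, n_gamma=6, n_lambda=3, seed=0,
    )


def make_run(params: PsychometricParams, seed: int, anchor: float | None = None,
             frequency_khz: float = 8.0):
    """One simulated 90-trial constant-stimuli run from a generating curve."""
    rng = np.random.default_rng(seed)
    design = design_psychometric_run(
        anchor if anchor is not None else params.alpha,
        seed=seed, frequency_khz=frequency_khz,
    )
    return simulate_run(design, params, rng)


@pytest.fixture
def study_params():
    """Generating parameters typical of the measured cohort."""
    return PsychometricParams(alpha=45.0, beta=0.14, gamma=0.02, lam=0.005)
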