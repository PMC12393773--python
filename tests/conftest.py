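import numpy as np
import pytest

from serialdep import synthetic as syn
from serialdep.io_core import AnalysisConfig


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down decoding config: the 148 ms sliding window of the
    published analysis is 4 samples at the 25 Hz simulation rate."""
    return AnalysisConfig(window_samples=4, decim=4)


@pytest.fixture(scope="session")
def meg_trials():
    trials = syn.generate_task_sequence("meg", 2, seed=11)
    return syn.generate_behavior(trials, syn.BehaviorParams(), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(
    trials,
    seed,
    shift=0.0,
    inducer="previous_target",
    shift_window=(-1.0, -0.2),
    n_sensors=16,
    gain=1.0,
    sfreq=25.0,
    span=(-1.4, 0.2),
    lock="response",
    noise=("spatially_correlated", 0.5),
):
    """One participant's synthetic epochs with an optional representational
    shift toward (+) / away from (-) the inducer inside shift_window."""
    params = syn.NeuralParams(
        n_sensors=n_sensors,
        tuning_gain=gain,
        noise_cov_spec=noise,
        bias_schedule=[(shift_window, inducer, shift)] if shift else [],
        signal_window=(span[0] + 0.1, span[1] - 0.1),
    )
    return syn.generate_epochs(trials, params, lock, span, sfreq, seed=seed)
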