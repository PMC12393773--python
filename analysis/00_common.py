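"""Shared constants for the numbered analysis drivers.

The simulated world: the two-grating MEG-style working-memory design
(400 trials per participant), reports with a 2 degree DoG attraction toward
the previous target and a 1 degree repulsion from sample 1, and
response-locked sensor epochs carrying an 8 degree attractive
representational shift toward the previous target from -1.0 to -0.2 s
before the report. Sampling is scaled to desk size (25 Hz, 16 sensors); the
148 ms sliding window of the full-scale analysis is 4 samples here.
"""

from pathlib import Path

from serialdep import synthetic as syn
from serialdep.io_core import AnalysisConfig

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SEED = 7
N_PARTICIPANTS = 6
SPAN, SFREQ, LOCK = (-1.4, 0.2), 25.0, "response"
SHIFT_WINDOW = (-1.0, -0.2)

CONFIG = AnalysisConfig(window_samples=4, decim=4, seed=SEED)
BEHAVIOR = syn.BehaviorParams()  # 2 deg prev attraction, -1 deg sample-1 bias
NEURAL = syn.NeuralParams(
    n_sensors=16,
    bias_schedule=[(SHIFT_WINDOW, "previous_target", 8.0)],
    signal_window=(-1.3, 0.1),
)
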