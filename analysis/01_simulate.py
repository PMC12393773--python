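"""Simulate the dataset every later stage analyses.

Generates task sequences, biased reports and orientation-tuned epochs for
6 participants of the two-grating MEG-style design, writes the epochs
containers and trial table under scratch/sim/, and a per-condition trial
count table under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

common = import_module("00_common")

from serialdep import synthetic as syn
from serialdep.io_core import write_epochs, write_trials


def main() -> None:
    common.SIM_DIR.mkdir(parents=True, exist_ok=True)
    common.RESULTS.mkdir(parents=True, exist_ok=True)

    trials = syn.generate_task_sequence("meg", common.N_PARTICIPANTS, seed=common.SEED)
    trials = syn.generate_behavior(trials, common.BEHAVIOR, seed=common.SEED + 1)
    write_trials(trials, common.SIM_DIR / "trials.tsv")

    for i, (pid, sub) in enumerate(trials.groupby("participant_id", sort=True)):
        ep = syn.generate_epochs(
            sub, common.NEURAL, common.LOCK, common.SPAN, common.SFREQ,
            seed=common.SEED + 100 + i,
        )
        write_epochs(ep, common.SIM_DIR / f"epochs_{pid}.h5")

    counts = trials.groupby(["condition", "cued_item"]).size().reset_index(name="n")
    counts.to_csv(common.RESULTS / "01_trial_counts.tsv", sep="\t", index=False)
    print(f"simulated {common.N_PARTICIPANTS} participants x 400 trials -> {common.SIM_DIR}")
    print(counts.to_string(index=False))
    print(
        "injected: +8 deg attractive shift toward the previous target, "
        f"{common.SHIFT_WINDOW[0]} to {common.SHIFT_WINDOW[1]} s before the report"
    )


if __name__ == "__main__":
    main()
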