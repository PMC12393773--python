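"""Neural bias of the target representation, sorted by inducer.

Sorts trials by whether the previous target (or the participant's own
report, as a control) was clockwise or counterclockwise of the current
target, differences the group asymmetry-index time courses, and tests the
window average where the attractive shift was injected.
"""

import json
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = import_module("00_common")

import numpy as np
import pandas as pd

from serialdep import behavior as beh
from serialdep import bias_analysis as ba
from serialdep import stats_inference as si
from serialdep.io_core import read_trials


def main() -> None:
    trials = read_trials(common.SIM_DIR / "trials.tsv")
    asym = pd.read_csv(common.SIM_DIR / "trial_asymmetry.tsv", sep="\t", na_values=["NA"])

    out_rows, window_tests = [], {}
    for inducer in ("previous_target", "report"):
        per_participant = []
        for pid, sub in asym.groupby("participant_id", sort=True):
            tsub = trials[trials.participant_id == pid]
            wide = sub.pivot(index="trial_id", columns="time", values="asymmetry")
            ids = wide.index.to_numpy()
            times = wide.columns.to_numpy(dtype=float)
            if inducer == "report":
                corrected, _ = beh.correct_stimulus_dependent_bias(
                    tsub["signed_error"].to_numpy(), tsub["target_orientation"].to_numpy()
                )
                cw, ccw, _ = ba.sort_by_inducer(tsub, "report", corrected_errors=corrected)
            else:
                cw, ccw, _ = ba.sort_by_inducer(tsub, inducer)
            bias = ba.neural_bias_timecourse(
                wide.to_numpy(dtype=float), ids, cw, ccw
            )
            for t, b in zip(times, bias):
                out_rows.append(
                    {"participant_id": pid, "inducer": inducer, "time": t, "bias": b}
                )
            per_participant.append(
                ba.fixed_window_mean(bias, times, *common.SHIFT_WINDOW)
            )
        t, p, df = si.window_ttest(np.array(per_participant))
        window_tests[inducer] = {
            "window_s": list(common.SHIFT_WINDOW),
            "mean_bias": float(np.mean(per_participant)),
            "t": t, "p": p, "df": df,
        }
        print(
            f"{inducer}-sorted bias in {common.SHIFT_WINDOW}: "
            f"mean {np.mean(per_participant):+.3f}, t({df})={t:.2f}, p={p:.4f}"
        )

    pd.DataFrame(out_rows).to_csv(
        common.RESULTS / "04_neural_bias.tsv", sep="\t", index=False, na_rep="NA"
    )
    (common.RESULTS / "04_window_tests.json").write_text(
        json.dumps(window_tests, indent=1)
    )
    ratio = (
        window_tests["report"]["mean_bias"]
        / window_tests["previous_target"]["mean_bias"]
    )
    print(
        "previous-target sorting recovers the injected attraction; the "
        f"report-sorted control retains only {100 * ratio:.0f}% of it — the "
        "residual reflects that simulated reports genuinely carry a 2 deg "
        "serial bias (report sorting is correlated with inducer sorting), "
        "not a probe-driven sensory signal, which this simulation omits"
    )


if __name__ == "__main__":
    main()
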