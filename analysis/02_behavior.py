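"""Behavioral serial bias: the model-free index per inducer.

Reads the simulated trial table, computes each participant's serial-bias
index for the previous-target and sample-1 inducers, the group t tests,
the 64-bin smoothed bias curves, and the correlation between
previous-target bias and mean absolute recall error.
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = import_module("00_common")

import numpy as np
import pandas as pd

from serialdep import behavior as beh
from serialdep import stats_inference as si
from serialdep.io_core import read_trials


def main() -> None:
    trials = read_trials(common.SIM_DIR / "trials.tsv")

    rows, curves = [], []
    for pid, sub in trials.groupby("participant_id", sort=True):
        mae = float(np.abs(sub["signed_error"]).mean())
        for inducer in ("previous_target", "sample1"):
            est = beh.participant_bias(sub, inducer)
            rows.append({**est.as_dict(), "mean_abs_error": mae})
            el = beh.eligible_trials(sub, inducer)
            deltas = beh.relative_orientation(
                el[
                    "previous_target_orientation"
                    if inducer == "previous_target"
                    else "sample1_orientation"
                ].to_numpy(dtype=float),
                el["target_orientation"].to_numpy(dtype=float),
            )
            centers, means = beh.smooth_bias_curve(
                el["signed_error"].to_numpy(dtype=float), deltas
            )
            curves.append(
                pd.DataFrame(
                    {"participant_id": pid, "inducer": inducer,
                     "bin_center": centers, "mean_error": means}
                )
            )

    tab = pd.DataFrame(rows)
    tab.to_csv(common.RESULTS / "02_behavior_bias.tsv", sep="\t", index=False)
    pd.concat(curves).to_csv(common.RESULTS / "02_bias_curves.tsv", sep="\t", index=False)

    for inducer in ("previous_target", "sample1"):
        x = tab.loc[tab.inducer == inducer, "index"].to_numpy()
        t, p, df = si.window_ttest(x)
        print(f"{inducer}: mean index {x.mean():+.2f} deg, t({df})={t:.2f}, p={p:.4f}")
    prev = tab[tab.inducer == "previous_target"]
    r, p = beh.bias_performance_correlation(prev["index"], prev["mean_abs_error"])
    print(f"previous-target bias vs mean |error|: r={r:.3f}, p={p:.3f} (n={len(prev)})")


if __name__ == "__main__":
    main()
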