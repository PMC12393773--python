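"""Cluster-based permutation inference on the group time courses.

Sign-flip cluster tests (10,000 iterations at desk scale; the full-scale
analysis uses 100,000) on target-decoding evidence and on the
previous-target neural-bias time course.
"""

import json
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = import_module("00_common")

import pandas as pd

from serialdep import stats_inference as si

N_PERM = 10_000


def main() -> None:
    out = {}
    for name, path, col, query in (
        ("evidence", common.RESULTS / "03_evidence.tsv", "evidence", None),
        ("prev_target_bias", common.RESULTS / "04_neural_bias.tsv", "bias",
         "inducer == 'previous_target'"),
    ):
        tab = pd.read_csv(path, sep="\t", na_values=["NA"])
        if query:
            tab = tab.query(query)
        wide = tab.pivot(index="participant_id", columns="time", values=col)
        res = si.cluster_permutation_test(
            wide.to_numpy(dtype=float),
            times=wide.columns.to_numpy(dtype=float),
            n_perm=N_PERM,
            cluster_alpha=common.CONFIG.cluster_alpha,
            seed=common.SEED,
        )
        out[name] = res.as_dict()
        print(f"{name}: {len(res.clusters)} cluster(s)")
        for c in res.clusters:
            print(
                f"  {c['t_start']:+.2f} to {c['t_end']:+.2f} s, "
                f"mass {c['mass']:.1f}, p={c['p']:.4f}"
            )

    (common.RESULTS / "05_clusters.json").write_text(json.dumps(out, indent=1))
    print(f"(n={common.N_PARTICIPANTS} participants; sign-flip null, {N_PERM} iterations)")


if __name__ == "__main__":
    main()
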