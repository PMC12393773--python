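"""Data model, file formats, configuration and pipeline orchestration.

Two on-disk containers tie the pipeline stages together:

* **Epochs container** — HDF5 with datasets ``/data`` (float32,
  trials × sensors × times), ``/times`` (float64, seconds relative to the
  lock event), ``/sfreq`` (scalar Hz), ``/trial_ids`` (int64),
  ``/sensors/ids`` (strings), ``/sensors/pos`` (float64, sensors × 2 or 3)
  and a root attribute ``lock_event``.
* **Trial table** — UTF-8 TSV, header mandatory, ``NA`` for missing values.

Orientations are stored in [0, 180) degrees; relative quantities in
(-90, 90]; time is in seconds with 0 at the lock event.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .circular import relative_orientation, wrap_orientation

logger = logging.getLogger("serialdep")

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigError",
    "DependencyError",
    "UndefinedEstimateError",
    "TRIAL_COLUMNS",
    "EpochsSet",
    "AnalysisConfig",
    "read_epochs",
    "write_epochs",
    "read_trials",
    "write_trials",
    "validate_trials",
    "run_pipeline",
]


class FormatError(ValueError):
    """A container on disk does not match the documented layout."""


class ValidationError(ValueError):
    """A table or tensor violates an invariant of the data model."""


class ConfigError(ValueError):
    """An analysis parameter is outside its documented domain."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested without its upstream outputs."""


class UndefinedEstimateError(ValueError):
    """An estimator has no defined value (e.g., an empty trial group)."""


# Canonical column order of the trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "trial_id",
    "block_id",
    "condition",
    "cued_item",
    "sample1_orientation",
    "sample2_orientation",
    "target_orientation",
    "previous_target_orientation",
    "report_orientation",
    "signed_error",
    "rt",
    "rotation_start",
    "first_in_block",
]

_ORIENTATION_COLS = [
    "sample1_orientation",
    "sample2_orientation",
    "target_orientation",
    "previous_target_orientation",
    "report_orientation",
]


# ---------------------------------------------------------------------------
# EpochsSet
# ---------------------------------------------------------------------------

@dataclass
class EpochsSet:
    """Trials × sensors × time tensor plus its axes and provenance.

    ``data`` is float32 (the on-disk dtype, so write/read round-trips are
    bit-exact). ``times`` is uniform with step 1/sfreq; sample ``i`` covers
    the half-open interval ``[times[i], times[i] + 1/sfreq)``.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    sensor_ids: list[str]
    sensor_pos: np.ndarray
    lock_event: str
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.sensor_pos = np.asarray(self.sensor_pos, dtype=np.float64)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        self.sensor_ids = [str(s) for s in self.sensor_ids]
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("data must be trials x sensors x times")
        n_tr, n_se, n_ti = self.data.shape
        if self.times.shape != (n_ti,):
            raise FormatError(
                f"times has {self.times.shape} entries; data has {n_ti} samples"
            )
        if len(self.sensor_ids) != n_se:
            raise FormatError(
                f"sensors/ids has {len(self.sensor_ids)} entries; data has {n_se} sensors"
            )
        if self.sensor_pos.shape[0] != n_se or self.sensor_pos.ndim != 2 or (
            self.sensor_pos.shape[1] not in (2, 3)
        ):
            raise FormatError("sensors/pos must be (n_sensors, 2 or 3)")
        if self.trial_ids.shape != (n_tr,):
            raise FormatError("trial_ids must align with the first data axis")
        if len(np.unique(self.trial_ids)) != n_tr:
            raise ValidationError("trial_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if n_ti > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(
                steps, 1.0 / self.sfreq, rtol=0, atol=1e-6 / self.sfreq
            ):
                raise ValidationError("times must increase uniformly at 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochsSet":
        return EpochsSet(
            data=self.data.copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            sensor_ids=list(self.sensor_ids),
            sensor_pos=self.sensor_pos.copy(),
            lock_event=self.lock_event,
            trial_ids=self.trial_ids.copy(),
        )

    def select_trials(self, mask_or_ids) -> "EpochsSet":
        """Subset trials by boolean mask or trial-id list."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            order = {tid: i for i, tid in enumerate(self.trial_ids)}
            idx = np.array([order[t] for t in arr], dtype=int)
        return EpochsSet(
            data=self.data[idx],
            times=self.times,
            sfreq=self.sfreq,
            sensor_ids=self.sensor_ids,
            sensor_pos=self.sensor_pos,
            lock_event=self.lock_event,
            trial_ids=self.trial_ids[idx],
        )

    def select_sensors(self, idx: Sequence[int]) -> "EpochsSet":
        idx = np.asarray(idx, dtype=int)
        return EpochsSet(
            data=self.data[:, idx, :],
            times=self.times,
            sfreq=self.sfreq,
            sensor_ids=[self.sensor_ids[i] for i in idx],
            sensor_pos=self.sensor_pos[idx],
            lock_event=self.lock_event,
            trial_ids=self.trial_ids,
        )


def write_epochs(epochs: EpochsSet, path) -> None:
    """Write an :class:`EpochsSet` to the HDF5 epochs container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times.astype(np.float64))
        f.create_dataset("sfreq", data=float(epochs.sfreq))
        f.create_dataset("trial_ids", data=epochs.trial_ids.astype(np.int64))
        grp = f.create_group("sensors")
        grp.create_dataset(
            "ids", data=np.array(epochs.sensor_ids, dtype=h5py.string_dtype())
        )
        grp.create_dataset("pos", data=epochs.sensor_pos.astype(np.float64))
        f.attrs["lock_event"] = epochs.lock_event


def read_epochs(path) -> EpochsSet:
    """Read the HDF5 epochs container; raises :class:`FormatError` on a
    missing dataset or a shape mismatch, naming the offending field."""
    path = Path(path)
    required = ["data", "times", "sfreq", "trial_ids", "sensors/ids", "sensors/pos"]
    with h5py.File(path, "r") as f:
        for name in required:
            if name not in f:
                raise FormatError(f"epochs container {path} lacks /{name}")
        if "lock_event" not in f.attrs:
            raise FormatError(f"epochs container {path} lacks attribute lock_event")
        data = f["data"][()]
        if data.ndim != 3:
            raise FormatError("/data must be 3-dimensional (trials x sensors x times)")
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sensors/ids"][()]]
        return EpochsSet(
            data=data,
            times=f["times"][()],
            sfreq=float(f["sfreq"][()]),
            sensor_ids=ids,
            sensor_pos=f["sensors/pos"][()],
            lock_event=str(f.attrs["lock_event"]),
            trial_ids=f["trial_ids"][()],
        )


# ---------------------------------------------------------------------------
# Trial table
# ---------------------------------------------------------------------------

def validate_trials(table: pd.DataFrame, check_signed_error: bool = True) -> pd.DataFrame:
    """Validate (and lightly normalize) a trial table in place.

    Orientations must parse to [0, 360); values in [180, 360) are reduced
    mod 180 with a logged warning; anything else raises
    :class:`ValidationError`. Where report and target are both present the
    stored ``signed_error`` must agree with
    ``relative_orientation(report, target)`` to 1e-6°; a missing
    ``signed_error`` is recomputed.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"trial table lacks columns: {missing}")

    for col in _ORIENTATION_COLS:
        vals = table[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.any((vals[finite] < 0) | (vals[finite] >= 360)):
            raise ValidationError(f"{col} contains orientations outside [0, 360)")
        over = finite & (vals >= 180)
        if np.any(over):
            logger.warning(
                "%s: %d orientation(s) in [180, 360) reduced mod 180", col, int(over.sum())
            )
            vals[over] = vals[over] % 180.0
            table[col] = vals

    table["first_in_block"] = table["first_in_block"].astype(bool)

    if check_signed_error:
        rep = table["report_orientation"].to_numpy(dtype=float)
        tgt = table["target_orientation"].to_numpy(dtype=float)
        both = np.isfinite(rep) & np.isfinite(tgt)
        expected = relative_orientation(rep[both], tgt[both])
        stored = table.loc[both, "signed_error"].to_numpy(dtype=float)
        have = np.isfinite(stored)
        if np.any(np.abs(stored[have] - np.asarray(expected)[have]) > 1e-6):
            raise ValidationError(
                "stored signed_error disagrees with relative_orientation(report, target)"
            )
        out = table["signed_error"].to_numpy(dtype=float)
        out[both] = expected
        table["signed_error"] = out
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table[TRIAL_COLUMNS].copy()
    out["first_in_block"] = out["first_in_block"].astype(bool)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    """Read and validate the TSV trial table."""
    table = pd.read_csv(
        Path(path), sep="\t", na_values=["NA"], keep_default_na=False, header=0
    )
    for col in ("trial_id", "block_id"):
        table[col] = table[col].astype(np.int64)
    for col in _ORIENTATION_COLS + ["signed_error", "rt", "rotation_start"]:
        table[col] = pd.to_numeric(table[col], errors="coerce").astype(float)
    table["first_in_block"] = table["first_in_block"].astype(str).str.lower().isin(
        ["true", "1"]
    )
    return validate_trials(table)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the decoding / bias pipeline.

    Defaults follow the published analysis: a 37-sample (148 ms at 250 Hz)
    sliding window, PCA keeping 90% of variance, 10 relative-orientation
    bins, asymmetry computed from the three clockwise bins (centers -63,
    -45, -27°) minus the three counterclockwise bins (+27, +45, +63°),
    100,000 permutation iterations and response-locked RT bounds of
    0.65–11.85 s.
    """

    window_samples: int = 37
    pca_variance: float = 0.90
    n_bins: int = 10
    asym_cw_bins: tuple = (1, 2, 3)
    asym_ccw_bins: tuple = (6, 7, 8)
    n_permutations: int = 100_000
    cluster_alpha: float = 0.05
    rt_bounds: tuple = (0.65, 11.85)
    seed: int = 0
    cov_estimator: str = "shrinkage"  # {"shrinkage", "identity"}
    pca_per_fold: bool = False  # True = leakage-free fold-wise PCA
    decim: int = 1  # decode every decim-th valid time sample

    def __post_init__(self) -> None:
        if self.window_samples < 1:
            raise ConfigError("window_samples must be >= 1")
        if not (0 < self.pca_variance <= 1):
            raise ConfigError("pca_variance must be in (0, 1]")
        if self.n_bins % 2 or self.n_bins < 2:
            raise ConfigError("n_bins must be a positive even integer")
        cw, ccw = set(self.asym_cw_bins), set(self.asym_ccw_bins)
        if cw & ccw:
            raise ConfigError("asymmetry bin sets must be disjoint")
        centers = self.bin_centers
        if not np.allclose(
            sorted(centers[sorted(cw)]), sorted(-centers[sorted(ccw)])
        ):
            raise ConfigError("asymmetry bin sets must be symmetric about 0°")
        if self.cov_estimator not in ("shrinkage", "identity"):
            raise ConfigError("cov_estimator must be 'shrinkage' or 'identity'")

    @property
    def bin_edges(self) -> np.ndarray:
        """Half-open [low, high) bin edges partitioning (-90, 90]."""
        return np.linspace(-90.0, 90.0, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return (e[:-1] + e[1:]) / 2.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("asym_cw_bins", "asym_ccw_bins", "rt_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

PIPELINE_STAGES = ("simulate", "behavior", "decode", "bias", "stats", "searchlight")


def _stage_log(stage: str, msg: str, *args) -> None:
    logger.info("[%s] " + msg, stage, *args)


def run_pipeline(
    config: AnalysisConfig,
    out_dir,
    stages: Sequence[str],
    trials_path: Optional[str] = None,
    epochs_paths: Optional[dict] = None,
    n_participants: int = 4,
    design: str = "meg",
    behavior_params=None,
    neural_params=None,
    sim_sfreq: float = 25.0,
    sim_span: tuple = (-1.4, 0.2),
    sim_lock: str = "response",
    searchlight_k: int = 6,
) -> dict:
    """Run the requested pipeline stages, writing TSV/JSON outputs plus a
    machine-readable run manifest under ``out_dir``.

    Returns the manifest dict. Stochastic stages draw all randomness from
    ``config.seed``, so reruns with the same config reproduce every output
    bit-exactly. Requesting a stage whose upstream outputs are neither in
    ``out_dir`` nor supplied as paths raises :class:`DependencyError`.
    """
    from . import behavior as beh
    from . import bias_analysis as ba
    from . import decoding as dec
    from . import stats_inference as si
    from . import synthetic as syn

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {},
    }

    behavior_params = behavior_params or syn.BehaviorParams()
    neural_params = neural_params or syn.NeuralParams()

    # ---- simulate -------------------------------------------------------
    if "simulate" in stages:
        rng_seed = config.seed
        trials = syn.generate_task_sequence(design, n_participants, seed=rng_seed)
        trials = syn.generate_behavior(trials, behavior_params, seed=rng_seed + 1)
        trials_path = str(out / "trials.tsv")
        write_trials(trials, trials_path)
        epochs_paths = {}
        for i, (pid, sub) in enumerate(trials.groupby("participant_id", sort=True)):
            ep = syn.generate_epochs(
                sub,
                neural_params,
                lock_event=sim_lock,
                epoch_span=sim_span,
                sfreq=sim_sfreq,
                seed=rng_seed + 100 + i,
            )
            p = out / f"epochs_{pid}.h5"
            write_epochs(ep, p)
            epochs_paths[pid] = str(p)
        manifest["outputs"]["simulate"] = {
            "trials": trials_path,
            "epochs": epochs_paths,
        }
        _stage_log("simulate", "%d participants, %d trials total", n_participants, len(trials))

    if trials_path is None:
        default = out / "trials.tsv"
        if default.exists():
            trials_path = str(default)

    def _need_trials() -> pd.DataFrame:
        if trials_path is None:
            raise DependencyError("stage requires a trial table; run 'simulate' or pass trials_path")
        return read_trials(trials_path)

    def _need_epochs() -> dict:
        nonlocal epochs_paths
        if epochs_paths is None:
            found = sorted(out.glob("epochs_*.h5"))
            if not found:
                raise DependencyError(
                    "stage requires epochs; run 'simulate' or pass epochs_paths"
                )
            epochs_paths = {p.stem.replace("epochs_", ""): str(p) for p in found}
        return epochs_paths

    # ---- behavior -------------------------------------------------------
    if "behavior" in stages:
        trials = _need_trials()
        rows = []
        for pid, sub in trials.groupby("participant_id", sort=True):
            for inducer in ("previous_target", "sample1"):
                try:
                    est = beh.participant_bias(sub, inducer)
                except UndefinedEstimateError:
                    continue
                rows.append(est.as_dict())
        bias_tab = pd.DataFrame(rows)
        p = out / "behavior_bias.tsv"
        bias_tab.to_csv(p, sep="\t", index=False, na_rep="NA")
        manifest["outputs"]["behavior"] = {"bias": str(p)}
        _stage_log("behavior", "%d bias estimates", len(rows))

    # ---- decode ---------------------------------------------------------
    if "decode" in stages:
        trials = _need_trials()
        paths = _need_epochs()
        ev_rows, asym_rows = [], []
        for pid in sorted(paths):
            sub = trials[trials["participant_id"] == pid]
            ep = read_epochs(paths[pid])
            res = dec.decode_timecourse(ep, sub, label="target", config=config)
            for t, v in zip(res.times, res.values):
                ev_rows.append({"participant_id": pid, "time": t, "evidence": v})
            asym = ba.asymmetry_from_curves(res.curves, config)
            for j, tid in enumerate(res.trial_ids):
                for k, t in enumerate(res.times):
                    asym_rows.append(
                        {
                            "participant_id": pid,
                            "trial_id": int(tid),
                            "time": t,
                            "asymmetry": asym[j, k],
                        }
                    )
        ev_path = out / "evidence.tsv"
        pd.DataFrame(ev_rows).to_csv(ev_path, sep="\t", index=False, na_rep="NA")
        asym_path = out / "trial_asymmetry.tsv"
        pd.DataFrame(asym_rows).to_csv(asym_path, sep="\t", index=False, na_rep="NA")
        manifest["outputs"]["decode"] = {
            "evidence": str(ev_path),
            "trial_asymmetry": str(asym_path),
        }
        _stage_log("decode", "evidence for %d participants", len(paths))

    # ---- bias -----------------------------------------------------------
    if "bias" in stages:
        asym_path = out / "trial_asymmetry.tsv"
        if not asym_path.exists():
            raise DependencyError("'bias' requires decode outputs (trial_asymmetry.tsv)")
        trials = _need_trials()
        asym = pd.read_csv(asym_path, sep="\t", na_values=["NA"])
        bias_tc = ba.bias_timecourse_table(asym, trials, inducer="previous_target")
        p = out / "neural_bias.tsv"
        bias_tc.to_csv(p, sep="\t", index=False, na_rep="NA")
        wide = bias_tc.pivot(index="participant_id", columns="time", values="bias")
        vals = wide.to_numpy(dtype=float)
        means = np.nanmean(vals, axis=1)
        t, pv, df = si.window_ttest(means[np.isfinite(means)])
        test_path = out / "neural_bias_test.json"
        test_path.write_text(json.dumps({"t": t, "p": pv, "df": df}, indent=1))
        manifest["outputs"]["bias"] = {"timecourse": str(p), "test": str(test_path)}
        _stage_log("bias", "t=%.3f p=%.4f df=%d", t, pv, df)

    # ---- stats ----------------------------------------------------------
    if "stats" in stages:
        bias_path = out / "neural_bias.tsv"
        ev_path = out / "evidence.tsv"
        source = bias_path if bias_path.exists() else ev_path
        if not source.exists():
            raise DependencyError("'stats' requires decode or bias outputs")
        tab = pd.read_csv(source, sep="\t", na_values=["NA"])
        value_col = "bias" if "bias" in tab.columns else "evidence"
        wide = tab.pivot(index="participant_id", columns="time", values=value_col)
        data = wide.to_numpy(dtype=float)
        times = wide.columns.to_numpy(dtype=float)
        res = si.cluster_permutation_test(
            data,
            times=times,
            n_perm=min(config.n_permutations, 10_000),
            cluster_alpha=config.cluster_alpha,
            seed=config.seed,
        )
        p = out / "clusters.json"
        p.write_text(json.dumps(res.as_dict(), indent=1))
        manifest["outputs"]["stats"] = {"clusters": str(p)}
        _stage_log("stats", "%d cluster(s)", len(res.clusters))

    # ---- searchlight ----------------------------------------------------
    if "searchlight" in stages:
        trials = _need_trials()
        paths = _need_epochs()
        maps = []
        for pid in sorted(paths):
            sub = trials[trials["participant_id"] == pid]
            ep = read_epochs(paths[pid])
            m = dec.searchlight_map(
                ep, sub, {"kind": "evidence", "label": "target"}, k=searchlight_k,
                config=config,
            )
            maps.append(m)
        topo = np.mean(maps, axis=0)
        ep0 = read_epochs(paths[sorted(paths)[0]])
        p = out / "searchlight.tsv"
        pd.DataFrame({"sensor_id": ep0.sensor_ids, "value": topo}).to_csv(
            p, sep="\t", index=False
        )
        manifest["outputs"]["searchlight"] = {"topography": str(p)}
        _stage_log("searchlight", "topography over %d sensors", len(topo))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
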