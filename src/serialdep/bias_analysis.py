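"""Neural-bias estimation from tuning-curve asymmetry.

The asymmetry index of a tuning curve is the mean similarity over the three
clockwise bins (centers -63, -45, -27°) minus the mean over the three
counterclockwise bins (+27, +45, +63°); positive = clockwise-shifted
representation. Trials are sorted by whether the inducer (previous target,
sample 1, or the participant's own report) was clockwise or
counterclockwise of the target; the neural bias index is
``asymmetry(CW-inducer trials) - asymmetry(CCW-inducer trials)``, so
attraction toward the inducer is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circular import relative_orientation
from .io_core import AnalysisConfig, ConfigError, UndefinedEstimateError, logger

__all__ = [
    "asymmetry_index",
    "asymmetry_from_curves",
    "sort_by_inducer",
    "neural_bias_timecourse",
    "fixed_window_mean",
    "per_trial_window_mean",
    "neural_bias_window",
    "bias_timecourse_table",
    "NeuralBiasResult",
]

_INDUCER_COL = {
    "previous_target": "previous_target_orientation",
    "sample1": "sample1_orientation",
    "report": "report_orientation",
}


def asymmetry_index(curve, config: Optional[AnalysisConfig] = None):
    """Clockwise minus counterclockwise mean similarity of a tuning curve.

    Accepts a :class:`~serialdep.decoding.TuningCurve`, a 10-vector, or an
    array whose last axis is bins. Invariant to mean-centering of the curve
    (both sides average the same number of bins).
    """
    config = config or AnalysisConfig()
    from .decoding import TuningCurve

    sims = curve.similarities if isinstance(curve, TuningCurve) else np.asarray(curve, dtype=float)
    cw = sims[..., list(config.asym_cw_bins)].mean(axis=-1)
    ccw = sims[..., list(config.asym_ccw_bins)].mean(axis=-1)
    out = cw - ccw
    return float(out) if np.ndim(out) == 0 else out


def asymmetry_from_curves(curves: np.ndarray, config: Optional[AnalysisConfig] = None) -> np.ndarray:
    """Per-trial, per-time asymmetry indices from a (trials, times, bins)
    stack of tuning curves (NaN where curves were missing)."""
    return asymmetry_index(np.asarray(curves, dtype=float), config)


def sort_by_inducer(trials: pd.DataFrame, inducer: str, corrected_errors=None):
    """Split trials into clockwise- and counterclockwise-inducer groups.

    Returns ``(cw_ids, ccw_ids, n_excluded)`` of trial ids. CW = the
    inducer's relative orientation to the target is negative; boundary
    trials at exactly 0° or +90° are excluded and counted. For
    ``inducer="report"`` pass the stimulus-bias-corrected signed errors
    (aligned with ``trials``); their sign then defines the groups.
    """
    if inducer not in _INDUCER_COL:
        raise ConfigError(f"unknown inducer {inducer!r}")
    if inducer == "report" and corrected_errors is not None:
        rel = np.asarray(corrected_errors, dtype=float)
    else:
        rel = relative_orientation(
            trials[_INDUCER_COL[inducer]].to_numpy(dtype=float),
            trials["target_orientation"].to_numpy(dtype=float),
        )
    ids = trials["trial_id"].to_numpy()
    finite = np.isfinite(rel)
    cw = finite & (rel < 0) & (rel > -90)
    ccw = finite & (rel > 0) & (rel < 90)
    n_excl = int(finite.sum() - cw.sum() - ccw.sum())
    if n_excl:
        logger.info("sort_by_inducer(%s): excluded %d boundary trial(s)", inducer, n_excl)
    if not cw.any() or not ccw.any():
        logger.warning("sort_by_inducer(%s): empty %s group", inducer, "cw" if not cw.any() else "ccw")
    return ids[cw], ids[ccw], n_excl


def _group_mean(asym: np.ndarray, trial_ids: np.ndarray, ids) -> np.ndarray:
    pos = {tid: i for i, tid in enumerate(trial_ids)}
    idx = [pos[t] for t in ids if t in pos]
    if not idx:
        raise UndefinedEstimateError("no trials of this group have tuning curves")
    with np.errstate(invalid="ignore"):
        return np.nanmean(asym[idx], axis=0)


def neural_bias_timecourse(
    asym: np.ndarray, trial_ids: np.ndarray, cw_ids, ccw_ids
) -> np.ndarray:
    """Per-time neural bias: mean asymmetry of CW-inducer trials minus mean
    asymmetry of CCW-inducer trials (group-then-average order). ``asym`` is
    (trials, times) aligned with ``trial_ids``."""
    return _group_mean(asym, trial_ids, cw_ids) - _group_mean(asym, trial_ids, ccw_ids)


def fixed_window_mean(values: np.ndarray, times: np.ndarray, t0: float, t1: float) -> float:
    """Mean of a time course over samples with t0 <= t < t1."""
    sel = (times >= t0) & (times < t1)
    if not sel.any():
        raise ConfigError(f"window ({t0}, {t1}) contains no samples")
    vals = np.asarray(values, dtype=float)[..., sel]
    with np.errstate(invalid="ignore"):
        if vals.ndim == 1:
            return float(np.nanmean(vals))
        per_trial = np.nanmean(vals, axis=-1)
        return float(np.nanmean(per_trial))


def per_trial_window_mean(
    asym: np.ndarray, times: np.ndarray, starts, stops
) -> tuple[float, int]:
    """Per-trial variable-window average: each trial is averaged over
    samples with ``start_i <= t < stop_i`` first, then over trials. Trials
    with an empty window are dropped and counted. Returns
    ``(mean, n_dropped)``."""
    asym = np.asarray(asym, dtype=float)
    starts = np.broadcast_to(np.asarray(starts, dtype=float), (asym.shape[0],))
    stops = np.asarray(stops, dtype=float)
    per_trial = np.full(asym.shape[0], np.nan)
    dropped = 0
    for i in range(asym.shape[0]):
        if not np.isfinite(stops[i]) or not np.isfinite(starts[i]):
            dropped += 1
            continue
        sel = (times >= starts[i]) & (times < stops[i])
        if not sel.any() or np.all(np.isnan(asym[i, sel])):
            dropped += 1
            continue
        per_trial[i] = np.nanmean(asym[i, sel])
    if dropped:
        logger.info("per_trial_window_mean: dropped %d trial(s) with empty windows", dropped)
    if np.all(np.isnan(per_trial)):
        raise UndefinedEstimateError("all trials have empty windows")
    return float(np.nanmean(per_trial)), dropped


def neural_bias_window(
    asym: np.ndarray,
    times: np.ndarray,
    trial_ids: np.ndarray,
    cw_ids,
    ccw_ids,
    window,
    rotation_start=None,
    event_start: float = None,
) -> float:
    """Windowed neural-bias scalar for one participant.

    ``window`` is ``("fixed", t0, t1)`` or ``("per_trial",)`` with
    ``event_start`` (scalar seconds) and per-trial ``rotation_start`` stops
    aligned with ``trial_ids``.
    """
    pos = {tid: i for i, tid in enumerate(trial_ids)}

    def group_value(ids) -> float:
        idx = [pos[t] for t in ids if t in pos]
        if not idx:
            raise UndefinedEstimateError("empty inducer group")
        if window[0] == "fixed":
            _, t0, t1 = window
            sel = (times >= t0) & (times < t1)
            with np.errstate(invalid="ignore"):
                per_trial = np.nanmean(asym[idx][:, sel], axis=-1)
            return float(np.nanmean(per_trial))
        mean, _ = per_trial_window_mean(
            asym[idx], times, event_start, np.asarray(rotation_start)[idx]
        )
        return mean

    return group_value(cw_ids) - group_value(ccw_ids)


@dataclass
class NeuralBiasResult:
    """Group-level neural-bias test: per-participant biases (positive =
    attraction) plus the one-sample t test against zero."""

    participant_ids: list
    biases: np.ndarray
    window: tuple
    t: float
    p: float
    df: int

    def as_dict(self) -> dict:
        return {
            "participant_ids": list(self.participant_ids),
            "biases": np.asarray(self.biases, dtype=float).tolist(),
            "window": list(self.window),
            "t": self.t,
            "p": self.p,
            "df": self.df,
        }


def bias_timecourse_table(
    asym_long: pd.DataFrame, trials: pd.DataFrame, inducer: str
) -> pd.DataFrame:
    """Long-format per-participant neural-bias time courses from a long
    table of per-trial asymmetries (columns participant_id, trial_id, time,
    asymmetry)."""
    rows = []
    for pid, sub in asym_long.groupby("participant_id", sort=True):
        tsub = trials[trials["participant_id"] == pid]
        cw, ccw, _ = sort_by_inducer(tsub, inducer)
        wide = sub.pivot(index="trial_id", columns="time", values="asymmetry")
        ids = wide.index.to_numpy()
        bias = neural_bias_timecourse(wide.to_numpy(dtype=float), ids, cw, ccw)
        for t, b in zip(wide.columns.to_numpy(dtype=float), bias):
            rows.append({"participant_id": pid, "time": t, "bias": b})
    return pd.DataFrame(rows)
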