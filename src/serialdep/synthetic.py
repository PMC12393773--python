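"""Synthetic task sequences, biased behavioral reports, and orientation-tuned
multichannel epochs.

The generator emulates two working-memory designs:

* ``meg`` — 400 trials per participant: 200 trials with both gratings shown
  (100 cued to sample 1, 100 to sample 2), 100 first-grating-only trials and
  100 second-grating-only trials, mixed randomly across 8 blocks of 50.
* ``eeg`` — cued recall with two gratings and an auditory retrocue: 2
  sessions x 6 cued-recall blocks x 84 trials = 1,008 trials per participant.

Reports carry a derivative-of-Gaussian (DoG) serial bias toward/away from
the previous trial's target, a within-trial DoG bias from sample 1, a
sinusoidal stimulus-dependent (cardinal) bias, occasional swap errors, and
circular Gaussian report noise. Sensor epochs carry cosine orientation
tuning whose represented orientation can be shifted toward or away from an
inducer inside configurable time windows, in spatially correlated noise.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circular import relative_orientation, wrap_orientation
from .io_core import ConfigError, TRIAL_COLUMNS, EpochsSet, logger, validate_trials

__all__ = [
    "BehaviorParams",
    "NeuralParams",
    "generate_task_sequence",
    "dog_kernel",
    "generate_behavior",
    "generate_epochs",
    "sensor_grid",
]


@dataclass
class BehaviorParams:
    """Parameters of the behavioral report generator.

    Amplitudes are in degrees and equal the peak shift of the DoG kernel
    (attraction positive). Defaults are typical of orientation
    working-memory reports: ~2° peak attraction toward the previous target,
    ~1° repulsion from sample 1, a 2° cardinal-bias term, and ~9° report
    noise. RTs are log-normal (median ≈ 2.5 s, 99% within ~0.7–6.5 s).
    """

    dog_amp_prev: float = 2.0
    dog_width_prev: float = 20.0
    dog_amp_s1: float = -1.0
    dog_width_s1: float = 20.0
    cardinal_amp: float = 2.0
    cardinal_freq: float = 2.0  # cycles per 180 deg
    report_noise_sd: float = 9.0
    swap_rate: float = 0.0
    rt_lognorm_mu: float = 0.9  # log-seconds
    rt_lognorm_sigma: float = 0.45

    def __post_init__(self) -> None:
        if self.dog_width_prev <= 0 or self.dog_width_s1 <= 0:
            raise ConfigError("DoG widths must be positive")
        if self.report_noise_sd <= 0:
            raise ConfigError("report_noise_sd must be positive")
        if not (0 <= self.swap_rate < 1):
            raise ConfigError("swap_rate must be in [0, 1)")


@dataclass
class NeuralParams:
    """Parameters of the sensor-epoch generator.

    ``bias_schedule`` lists ``(window, inducer, shift_deg)`` entries: within
    ``window`` (seconds, half-open) the represented orientation is shifted
    by ``shift_deg`` toward (+) or away from (-) the inducer, i.e., along
    ``sign(relative_orientation(inducer, target))``. ``signal_window`` is
    the span carrying orientation tuning (``None`` = whole epoch). Shift
    and signal windows get 50 ms cosine ramps at their edges.
    """

    n_sensors: int = 16
    tuning_gain: float = 1.0
    tuning_width: Optional[float] = None  # None = cosine tuning profile
    noise_cov_spec: tuple = ("spatially_correlated", 0.5)
    noise_sd: float = 1.0
    bias_schedule: list = field(default_factory=list)
    signal_window: Optional[tuple] = None
    ramp_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.n_sensors < 2:
            raise ConfigError("need at least 2 sensors")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if isinstance(self.noise_cov_spec, str):
            if self.noise_cov_spec != "diagonal":
                raise ConfigError("noise_cov_spec string form must be 'diagonal'")
        else:
            kind, rho = self.noise_cov_spec
            if kind != "spatially_correlated" or not (0 <= rho < 1):
                raise ConfigError(
                    "noise_cov_spec must be 'diagonal' or ('spatially_correlated', rho in [0,1))"
                )
        for window, inducer, shift in self.bias_schedule:
            if abs(shift) >= 90:
                raise ConfigError("|shift_deg| must be < 90")
            if inducer not in ("previous_target", "sample1"):
                raise ConfigError(f"unknown bias inducer {inducer!r}")


# ---------------------------------------------------------------------------
# Task sequences
# ---------------------------------------------------------------------------

_MEG_BLOCKS = 8  # not stated in the source design; 8 blocks of 50 trials


def _link_previous_target(df: pd.DataFrame) -> pd.DataFrame:
    prev = df["target_orientation"].shift(1)
    new_block = df["block_id"] != df["block_id"].shift(1)
    df["previous_target_orientation"] = np.where(new_block, np.nan, prev)
    df["first_in_block"] = new_block.to_numpy(dtype=bool)
    return df


def _meg_sequence(rng: np.random.Generator, pid: str) -> pd.DataFrame:
    conditions = (
        ["both_shown"] * 200 + ["first_only"] * 100 + ["second_only"] * 100
    )
    cued = ["sample1"] * 100 + ["sample2"] * 100 + ["sample1"] * 100 + ["sample2"] * 100
    order = rng.permutation(400)
    conditions = [conditions[i] for i in order]
    cued = [cued[i] for i in order]

    s1 = rng.uniform(0.0, 180.0, size=400)
    s2 = rng.uniform(0.0, 180.0, size=400)
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "trial_id": np.arange(400, dtype=np.int64),
            "block_id": np.repeat(np.arange(_MEG_BLOCKS), 400 // _MEG_BLOCKS),
            "condition": conditions,
            "cued_item": cued,
            "sample1_orientation": s1,
            "sample2_orientation": s2,
        }
    )
    df.loc[df["condition"] == "second_only", "sample1_orientation"] = np.nan
    df.loc[df["condition"] == "first_only", "sample2_orientation"] = np.nan
    df["target_orientation"] = np.where(
        df["cued_item"] == "sample1",
        df["sample1_orientation"],
        df["sample2_orientation"],
    )
    return _link_previous_target(df)


def _eeg_sequence(rng: np.random.Generator, pid: str) -> pd.DataFrame:
    n_blocks, per_block = 12, 84  # 2 sessions x 6 cued-recall blocks
    frames = []
    for b in range(n_blocks):
        cue = np.array(["sample1"] * (per_block // 2) + ["sample2"] * (per_block // 2))
        rng.shuffle(cue)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial_id": np.arange(per_block, dtype=np.int64) + b * per_block,
                    "block_id": b,
                    "condition": "cued_recall",
                    "cued_item": cue,
                    "sample1_orientation": rng.uniform(0.0, 180.0, per_block),
                    "sample2_orientation": rng.uniform(0.0, 180.0, per_block),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["target_orientation"] = np.where(
        df["cued_item"] == "sample1",
        df["sample1_orientation"],
        df["sample2_orientation"],
    )
    return _link_previous_target(df)


def generate_task_sequence(design: str, n_participants: int, seed: int) -> pd.DataFrame:
    """Generate per-participant trial sequences for the ``meg`` or ``eeg``
    design with i.i.d. uniform orientations on [0, 180)."""
    if design not in ("meg", "eeg"):
        raise ConfigError(f"unknown design {design!r}")
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        pid = f"sub{p:02d}"
        df = _meg_sequence(rng, pid) if design == "meg" else _eeg_sequence(rng, pid)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    for col in ("report_orientation", "signed_error", "rt", "rotation_start"):
        df[col] = np.nan
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# Behavioral reports
# ---------------------------------------------------------------------------

def dog_kernel(delta, amplitude: float, width: float):
    """First-derivative-of-Gaussian serial-bias kernel.

    ``a * (delta/w) * exp(1/2 - delta^2 / (2 w^2))`` — an odd function of
    ``delta`` whose peak shift equals ``amplitude`` (in degrees) and occurs
    at ``|delta| == width``.
    """
    if width <= 0:
        raise ConfigError("width must be positive")
    d = np.asarray(delta, dtype=float)
    out = amplitude * (d / width) * np.exp(0.5 - d**2 / (2.0 * width**2))
    return float(out) if out.ndim == 0 else out


def _cardinal_bias(theta, amp: float, freq: float):
    return amp * np.sin(2.0 * np.pi * freq * np.asarray(theta, dtype=float) / 180.0)


def generate_behavior(
    trials: pd.DataFrame, params: BehaviorParams, seed: int
) -> pd.DataFrame:
    """Fill reports, signed errors, RTs and rotation-start times.

    The signed report error is the sum of a DoG bias toward the previous
    target, a DoG bias from sample 1 (on trials where sample 1 was shown
    but sample 2 was cued), a sinusoidal stimulus-dependent bias, and
    Gaussian noise. With probability ``swap_rate`` (when the uncued item
    exists) the report is centered on the uncued item instead. Rotation
    start is a Beta(2,2) fraction of the RT, so 0 < rotation_start < rt.
    """
    rng = np.random.default_rng(seed)
    df = trials.copy().reset_index(drop=True)
    n = len(df)
    target = df["target_orientation"].to_numpy(dtype=float)
    prev = df["previous_target_orientation"].to_numpy(dtype=float)
    s1 = df["sample1_orientation"].to_numpy(dtype=float)
    s2 = df["sample2_orientation"].to_numpy(dtype=float)
    cued2 = (df["cued_item"] == "sample2").to_numpy()

    err = np.zeros(n)
    has_prev = np.isfinite(prev)
    err[has_prev] += dog_kernel(
        relative_orientation(prev[has_prev], target[has_prev]),
        params.dog_amp_prev,
        params.dog_width_prev,
    )
    s1_applies = cued2 & np.isfinite(s1)
    err[s1_applies] += dog_kernel(
        relative_orientation(s1[s1_applies], target[s1_applies]),
        params.dog_amp_s1,
        params.dog_width_s1,
    )
    err += _cardinal_bias(target, params.cardinal_amp, params.cardinal_freq)
    err += rng.normal(0.0, params.report_noise_sd, size=n)

    report = wrap_orientation(target + err)

    # swap errors: report the uncued item (plus noise) instead
    uncued = np.where(cued2, s1, s2)
    swappable = np.isfinite(uncued)
    swaps = swappable & (rng.uniform(size=n) < params.swap_rate)
    if swaps.any():
        report[swaps] = wrap_orientation(
            uncued[swaps] + rng.normal(0.0, params.report_noise_sd, size=int(swaps.sum()))
        )
        logger.info("generate_behavior: %d swap reports", int(swaps.sum()))

    df["report_orientation"] = report
    df["signed_error"] = relative_orientation(report, target)
    rt = rng.lognormal(params.rt_lognorm_mu, params.rt_lognorm_sigma, size=n)
    df["rt"] = rt
    df["rotation_start"] = rt * rng.beta(2.0, 2.0, size=n)
    return validate_trials(df)


# ---------------------------------------------------------------------------
# Sensor epochs
# ---------------------------------------------------------------------------

def sensor_grid(n_sensors: int) -> np.ndarray:
    """Positions of ``n_sensors`` sensors on a unit-spaced grid on a disc:
    the grid points closest to the origin, ties broken deterministically."""
    side = int(np.ceil(np.sqrt(n_sensors))) + 2
    ax = np.arange(-side, side + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    d = np.linalg.norm(pts, axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], np.round(d, 9)))
    return pts[order[:n_sensors]]


def _window_envelope(times: np.ndarray, window, ramp_s: float) -> np.ndarray:
    """1 inside ``window`` (half-open, seconds) with cosine ramps of length
    ``ramp_s`` just inside each edge; 0 outside."""
    t0, t1 = window
    env = np.zeros_like(times)
    inside = (times >= t0) & (times < t1)
    env[inside] = 1.0
    if ramp_s > 0:
        rise = inside & (times < t0 + ramp_s)
        env[rise] = 0.5 - 0.5 * np.cos(np.pi * (times[rise] - t0) / ramp_s)
        fall = inside & (times >= t1 - ramp_s)
        env[fall] = np.minimum(
            env[fall], 0.5 - 0.5 * np.cos(np.pi * (t1 - times[fall]) / ramp_s)
        )
    return env


def _noise_chol(params: NeuralParams, pos: np.ndarray) -> Optional[np.ndarray]:
    if isinstance(params.noise_cov_spec, str):  # diagonal
        return None
    _, rho = params.noise_cov_spec
    if rho == 0:
        return None
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = params.noise_sd**2 * rho**d
    cov[np.diag_indices_from(cov)] = params.noise_sd**2
    return np.linalg.cholesky(cov + 1e-10 * np.eye(len(pos)))


def generate_epochs(
    trials: pd.DataFrame,
    params: NeuralParams,
    lock_event: str,
    epoch_span: tuple,
    sfreq: float,
    seed: int,
) -> EpochsSet:
    """Generate one participant's trials × sensors × time tensor.

    Within the signal window, sensor ``s`` (preferred orientation φ_s,
    preferences evenly spread over [0, 180)) carries
    ``gain * cos(2·(θ_repr − φ_s))`` plus noise, where θ_repr is the target
    orientation shifted by each applicable ``bias_schedule`` entry along the
    sign of ``relative_orientation(inducer, target)``. Outside all windows
    the data are pure noise with the configured spatial covariance.
    """
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ConfigError("generate_epochs expects a single participant's trials")
    rng = np.random.default_rng(seed)

    t0, t1 = float(epoch_span[0]), float(epoch_span[1])
    n_times = int(round((t1 - t0) * sfreq))
    times = t0 + np.arange(n_times) / sfreq
    epoch_lo, epoch_hi = times[0], times[-1] + 1.0 / sfreq

    signal_window = params.signal_window or (t0, t1)
    for window, _, _ in params.bias_schedule:
        if window[0] < epoch_lo - 1e-9 or window[1] > epoch_hi + 1e-9:
            raise ConfigError(f"bias window {window} lies outside the epoch")
    if signal_window[0] < epoch_lo - 1e-9 or signal_window[1] > epoch_hi + 1e-9:
        raise ConfigError(f"signal window {signal_window} lies outside the epoch")

    n = len(trials)
    target = trials["target_orientation"].to_numpy(dtype=float)
    ramp_s = params.ramp_ms / 1000.0

    # represented orientation per (trial, time)
    shift = np.zeros((n, n_times))
    for window, inducer, shift_deg in params.bias_schedule:
        col = {"previous_target": "previous_target_orientation", "sample1": "sample1_orientation"}[inducer]
        ind = trials[col].to_numpy(dtype=float)
        sgn = np.sign(relative_orientation(ind, target))
        sgn[~np.isfinite(ind)] = 0.0
        env = _window_envelope(times, window, ramp_s)
        shift += np.outer(sgn * shift_deg, env)
    theta_repr = target[:, None] + shift  # (n, n_times)

    pos = sensor_grid(params.n_sensors)
    phi = 180.0 * np.arange(params.n_sensors) / params.n_sensors
    sig_env = _window_envelope(times, signal_window, ramp_s)

    # (n, n_sensors, n_times)
    angle = theta_repr[:, None, :] - phi[None, :, None]
    if params.tuning_width is None:
        pattern = np.cos(2.0 * np.deg2rad(angle))
    else:
        prof = np.exp(
            -np.square(relative_orientation(angle, 0.0)) / (2.0 * params.tuning_width**2)
        )
        pattern = prof - prof.mean(axis=1, keepdims=True)
    data = params.tuning_gain * sig_env[None, None, :] * pattern

    chol = _noise_chol(params, pos)
    noise = rng.standard_normal((n, params.n_sensors, n_times))
    if chol is None:
        data += params.noise_sd * noise
    else:
        data += np.einsum("ij,njt->nit", chol, noise)

    return EpochsSet(
        data=data.astype(np.float32),
        times=times,
        sfreq=float(sfreq),
        sensor_ids=[f"S{i:03d}" for i in range(params.n_sensors)],
        sensor_pos=pos,
        lock_event=lock_event,
        trial_ids=trials["trial_id"].to_numpy(dtype=np.int64),
    )
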