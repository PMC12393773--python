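"""Model-free behavioral serial-bias estimation.

The serial-bias index is the mean signed report error on trials where the
inducer (previous target, sample 1, ...) lies up to 45° counterclockwise of
the target minus the mean error on trials where it lies up to 45° clockwise.
Positive index = attraction toward the inducer. Trials with the inducer
exactly at 0° relative orientation are excluded from both sides.

Also provides the overlapping-bin smoother used for visualization, the
three-sinusoid correction for stimulus-dependent (cardinal/oblique) report
biases, and the bias-vs-performance Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .circular import relative_orientation
from .io_core import ConfigError, UndefinedEstimateError, logger

__all__ = [
    "BiasEstimate",
    "relative_orientation",
    "serial_bias_index",
    "participant_bias",
    "smooth_bias_curve",
    "fit_stimulus_bias",
    "correct_stimulus_dependent_bias",
    "bias_performance_correlation",
]


@dataclass
class BiasEstimate:
    """Per-participant serial-bias index with the trial counts behind it."""

    participant_id: str
    inducer: str
    index: float
    n_cw: int
    n_ccw: int

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "inducer": self.inducer,
            "index": self.index,
            "n_cw": self.n_cw,
            "n_ccw": self.n_ccw,
        }


def serial_bias_index(errors, deltas) -> tuple[float, int, int]:
    """Two-sided mean-error difference over the ±45° inducer window.

    ``index = mean(error | delta in (0, 45]) - mean(error | delta in [-45, 0))``

    where ``delta`` is the inducer orientation relative to the target in
    (-90, 90]. Returns ``(index, n_cw, n_ccw)``; raises
    :class:`UndefinedEstimateError` naming the empty side if either group
    has no trials.
    """
    errors = np.asarray(errors, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    ok = np.isfinite(errors) & np.isfinite(deltas)
    errors, deltas = errors[ok], deltas[ok]
    if np.any(deltas <= -90) or np.any(deltas > 90):
        raise ValueError("deltas must lie in (-90, 90]")
    ccw = (deltas > 0) & (deltas <= 45)
    cw = (deltas < 0) & (deltas >= -45)
    if not ccw.any():
        raise UndefinedEstimateError("no trials with inducer in (0, 45] (ccw side)")
    if not cw.any():
        raise UndefinedEstimateError("no trials with inducer in [-45, 0) (cw side)")
    index = float(errors[ccw].mean() - errors[cw].mean())
    return index, int(cw.sum()), int(ccw.sum())


_INDUCER_COL = {
    "previous_target": "previous_target_orientation",
    "sample1": "sample1_orientation",
    "sample2_on_sample1": "sample2_orientation",
}


def eligible_trials(trials: pd.DataFrame, inducer: str) -> pd.DataFrame:
    """Trials entering the bias estimate for a given inducer.

    previous_target: every trial with a linked previous target and a report.
    sample1: both samples shown, sample 2 cued (sample 1 is the bystander).
    sample2_on_sample1: both samples shown, sample 1 cued.
    """
    if inducer not in _INDUCER_COL:
        raise ConfigError(f"unknown inducer {inducer!r}")
    m = trials["report_orientation"].notna() & trials[_INDUCER_COL[inducer]].notna()
    if inducer == "sample1":
        m &= trials["sample1_orientation"].notna() & (trials["cued_item"] == "sample2")
    elif inducer == "sample2_on_sample1":
        m &= trials["sample2_orientation"].notna() & (trials["cued_item"] == "sample1")
    return trials[m]


def participant_bias(trials: pd.DataFrame, inducer: str) -> BiasEstimate:
    """Serial-bias index for one participant's trial table."""
    pid = trials["participant_id"].iloc[0] if len(trials) else ""
    sub = eligible_trials(trials, inducer)
    deltas = relative_orientation(
        sub[_INDUCER_COL[inducer]].to_numpy(dtype=float),
        sub["target_orientation"].to_numpy(dtype=float),
    )
    index, n_cw, n_ccw = serial_bias_index(sub["signed_error"].to_numpy(dtype=float), deltas)
    return BiasEstimate(str(pid), inducer, index, n_cw, n_ccw)


def smooth_bias_curve(errors, deltas, n_bins: int = 64, frac: float = 0.25):
    """Overlapping-bin smoother for serial-bias curves (visualization only).

    Bins the inducer-relative orientation into ``n_bins`` evenly spaced,
    overlapping bins over (-90, 90]; each bin averages the ``frac * N``
    trials circularly closest to its center. Returns
    ``(bin_centers, mean_errors)``.
    """
    errors = np.asarray(errors, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    ok = np.isfinite(errors) & np.isfinite(deltas)
    errors, deltas = errors[ok], deltas[ok]
    m = int(round(frac * len(errors)))
    if m < 1:
        raise ConfigError("frac * N must be at least 1 trial per bin")
    centers = -90.0 + 180.0 * (np.arange(n_bins) + 1) / n_bins
    means = np.empty(n_bins)
    for i, c in enumerate(centers):
        dist = np.abs(relative_orientation(deltas, c))
        nearest = np.argpartition(dist, m - 1)[:m]
        means[i] = errors[nearest].mean()
    return centers, means


# ---------------------------------------------------------------------------
# Stimulus-dependent (cardinal/oblique) bias correction
# ---------------------------------------------------------------------------

def _sinusoid_design(targets: np.ndarray, freqs) -> np.ndarray:
    cols = []
    for f in freqs:
        arg = 2.0 * np.pi * f * targets / 180.0
        cols.append(np.sin(arg))
        cols.append(np.cos(arg))
    return np.column_stack(cols)


def fit_stimulus_bias(errors, targets, max_harmonic: int = 8):
    """Fit a sum of three sinusoids of the target orientation to the errors.

    Deterministic multi-start: every 3-subset of integer harmonics
    1..max_harmonic (cycles per 180°) is fit by linear least squares
    (amplitude and phase are linear once frequency is fixed); the best
    subset seeds a nonlinear refinement with free frequencies. Returns
    ``(fitted_values, info)`` where ``info`` records frequencies, RSS and a
    convergence flag. The fit RSS never exceeds the zero-model RSS.
    """
    from itertools import combinations

    errors = np.asarray(errors, dtype=float)
    targets = np.asarray(targets, dtype=float)
    rss0 = float(np.sum(errors**2))

    best = (np.inf, None, None)  # rss, freqs, coefs
    for freqs in combinations(range(1, max_harmonic + 1), 3):
        X = _sinusoid_design(targets, freqs)
        coef, *_ = np.linalg.lstsq(X, errors, rcond=None)
        rss = float(np.sum((errors - X @ coef) ** 2))
        if rss < best[0]:
            best = (rss, np.array(freqs, dtype=float), coef)
    rss, freqs, coef = best

    def model(params):
        f = params[:3]
        c = params[3:]
        return _sinusoid_design(targets, f) @ c

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.least_squares(
                lambda p: model(p) - errors,
                x0=np.concatenate([freqs, coef]),
                method="lm",
                max_nfev=2000,
            )
        if res.success and 2 * res.cost < rss:
            freqs, coef, rss = res.x[:3], res.x[3:], 2 * float(res.cost)
    except Exception:  # pragma: no cover - fallback to the grid solution
        converged = False
        logger.warning("sinusoid refinement failed; keeping grid fit")

    fitted = _sinusoid_design(targets, freqs) @ coef
    if rss > rss0 + 1e-9:  # cannot happen for the linear fit; safety net
        fitted = np.zeros_like(errors)
        rss = rss0
        converged = False
        logger.warning("stimulus-bias fit worse than zero model; identity correction")
    info = {"freqs": np.sort(np.abs(freqs)).tolist(), "rss": rss, "converged": converged}
    return fitted, info


def correct_stimulus_dependent_bias(errors, targets, max_harmonic: int = 8):
    """Remove the fitted stimulus-dependent bias from the signed errors.

    Returns ``(corrected_errors, info)``; ``corrected = errors - fit(target)``.
    """
    errors = np.asarray(errors, dtype=float)
    if not len(errors) or np.allclose(errors, 0.0):
        return errors.copy(), {"freqs": [], "rss": 0.0, "converged": True}
    fitted, info = fit_stimulus_bias(errors, targets, max_harmonic=max_harmonic)
    return errors - fitted, info


def bias_performance_correlation(per_participant_bias, per_participant_mean_abs_error):
    """Pearson correlation (r, two-sided p) between participants' serial-bias
    index and their mean absolute recall error."""
    r, p = stats.pearsonr(
        np.asarray(per_participant_bias, dtype=float),
        np.asarray(per_participant_mean_abs_error, dtype=float),
    )
    return float(r), float(p)
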