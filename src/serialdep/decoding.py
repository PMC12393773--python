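"""Cross-validated Mahalanobis tuning-curve decoding of orientation.

For every time point, sensor data inside a trailing sliding window are
concatenated into one feature vector per trial and reduced by PCA. Each
trial is then held out in turn: training trials are binned by their
orientation *relative to the held-out trial* into 10 half-open 18° bins,
and the Mahalanobis distances from the held-out pattern to the 10 bin-mean
patterns are sign-reversed and mean-centered, yielding a tuning curve
centered on the test orientation. Projecting the curve onto a cos(2θ)
profile gives the decoding evidence; an unshifted representation peaks in
the two central bins.

The Mahalanobis covariance is a Ledoit–Wolf-style shrinkage estimate of the
training-fold residuals (per-bin means removed), or the identity for
oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg, stats
from scipy.ndimage import gaussian_filter1d

from .circular import relative_orientation
from .io_core import ConfigError, AnalysisConfig, EpochsSet, logger

__all__ = [
    "TuningCurve",
    "EvidenceTimecourse",
    "preprocess_epochs",
    "build_features",
    "reduce_dimensionality",
    "shrinkage_covariance",
    "mahalanobis_distance",
    "tuning_curve_loo",
    "tuning_curves_loo_all",
    "decoding_evidence",
    "decode_timecourse",
    "response_lock",
    "searchlight_map",
    "topography_correlation",
    "LABEL_COLUMNS",
]

LABEL_COLUMNS = {
    "target": "target_orientation",
    "previous_target": "previous_target_orientation",
    "sample1": "sample1_orientation",
    "sample2": "sample2_orientation",
    "report": "report_orientation",
}


@dataclass
class TuningCurve:
    """Mean-centered, sign-reversed Mahalanobis distances over the 10
    relative-orientation bins (centers -81 ... +81°, edges half-open)."""

    similarities: np.ndarray
    bin_centers: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.similarities = np.asarray(self.similarities, dtype=float)


@dataclass
class EvidenceTimecourse:
    """Per-participant decoding-evidence time series, with the per-trial
    tuning curves it was computed from."""

    values: np.ndarray  # (n_times,) mean evidence over trials
    times: np.ndarray
    lock_event: str
    label: str
    trial_ids: np.ndarray
    evidence_per_trial: np.ndarray = field(default=None)  # (n_trials, n_times)
    curves: np.ndarray = field(default=None)  # (n_trials, n_times, n_bins)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_epochs(epochs: EpochsSet, steps: Sequence) -> EpochsSet:
    """Apply light preprocessing steps in the listed order.

    Steps: ``("gaussian_smooth", sd_ms)``, ``"remove_cross_trial_mean"``,
    ``("baseline_regress", (t0, t1))`` and ``"unit_variance"``.
    ``baseline_regress`` regresses the per-trial mean signal in the baseline
    window out of every (sensor, time) cell across trials, separately per
    sensor; ``unit_variance`` scales every cell to unit across-trial
    variance.
    """
    out = epochs.copy()
    data = out.data.astype(np.float64)
    for step in steps:
        name, arg = step if isinstance(step, (tuple, list)) else (step, None)
        if name == "gaussian_smooth":
            sigma = float(arg) / 1000.0 * out.sfreq
            data = gaussian_filter1d(data, sigma=sigma, axis=2, mode="nearest")
        elif name == "remove_cross_trial_mean":
            data -= data.mean(axis=0, keepdims=True)
        elif name == "baseline_regress":
            t0, t1 = arg
            sel = (out.times >= t0) & (out.times < t1)
            if not sel.any():
                raise ConfigError(f"baseline window {arg} outside the epoch")
            b = data[:, :, sel].mean(axis=2)  # (trials, sensors)
            bc = b - b.mean(axis=0, keepdims=True)
            xc = data - data.mean(axis=0, keepdims=True)
            denom = np.sum(bc**2, axis=0)  # (sensors,)
            denom[denom == 0] = 1.0
            slope = np.einsum("is,ist->st", bc, xc) / denom[:, None]
            data = xc - bc[:, :, None] * slope[None, :, :]
        elif name == "unit_variance":
            sd = data.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            data = data / sd
        else:
            raise ConfigError(f"unknown preprocessing step {name!r}")
    out.data = data.astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# Features and PCA
# ---------------------------------------------------------------------------

def build_features(epochs: EpochsSet, t_index: int, window_samples: int = 37) -> np.ndarray:
    """Trial × (sensors · window) feature matrix for the trailing window
    ending at ``t_index`` (inclusive)."""
    start = t_index - window_samples + 1
    if start < 0 or t_index >= epochs.n_times:
        raise ConfigError(
            f"window of {window_samples} samples ending at index {t_index} "
            "is truncated by the epoch edge"
        )
    block = epochs.data[:, :, start : t_index + 1].astype(np.float64)
    return block.reshape(epochs.n_trials, -1)


class PCAReducer:
    """PCA transform retaining the smallest number of components whose
    cumulative explained-variance ratio reaches the requested fraction.
    Reusable on held-out rows."""

    def __init__(self, variance: float = 0.90):
        if not (0 < variance <= 1):
            raise ConfigError("variance must be in (0, 1]")
        self.variance = variance
        self.mean_ = None
        self.components_ = None
        self.k = None

    def fit(self, X: np.ndarray) -> "PCAReducer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 rows")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # economy SVD; eigvals of covariance = s^2 / (n-1)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        ev = s**2
        total = ev.sum()
        if total == 0:
            self.k = 1
            self.components_ = Vt[:1]
            return self
        ratio = np.cumsum(ev) / total
        self.k = int(np.searchsorted(ratio, self.variance - 1e-12) + 1)
        self.k = min(self.k, int(np.sum(ev > total * 1e-12)) or 1)
        self.components_ = Vt[: self.k]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T


def reduce_dimensionality(features: np.ndarray, variance: float = 0.90):
    """Fit PCA on the feature matrix; returns ``(scores, reducer)`` where
    ``reducer.transform`` is reusable on held-out rows and ``reducer.k`` is
    the retained dimensionality."""
    red = PCAReducer(variance).fit(features)
    return red.transform(features), red


# ---------------------------------------------------------------------------
# Mahalanobis machinery
# ---------------------------------------------------------------------------

def shrinkage_covariance(residuals: np.ndarray) -> np.ndarray:
    """Ledoit–Wolf shrinkage covariance of (already centered) residuals:
    the empirical covariance shrunk toward a scaled identity with the
    analytically optimal intensity."""
    R = np.asarray(residuals, dtype=float)
    n, p = R.shape
    S = R.T @ R / n
    mu = np.trace(S) / p
    delta2 = np.sum((S - mu * np.eye(p)) ** 2)
    norms4 = np.sum(np.sum(R**2, axis=1) ** 2)
    beta_bar = (norms4 / n - np.sum(S**2)) / n
    beta2 = min(beta_bar, delta2)
    alpha = 0.0 if delta2 <= 0 else beta2 / delta2
    return alpha * mu * np.eye(p) + (1.0 - alpha) * S


def mahalanobis_distance(x, y, cov) -> float:
    """sqrt((x - y)^T cov^{-1} (x - y)) for a symmetric positive-definite
    covariance; raises a numerical error if the covariance is singular."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    try:
        c, low = linalg.cho_factor(np.asarray(cov, dtype=float))
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular covariance: {e}") from e
    d2 = diff @ linalg.cho_solve((c, low), diff)
    return float(np.sqrt(max(d2, 0.0)))


def _bin_index(rel: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Half-open [low, high) bin of relative orientations in (-90, 90];
    +90 falls in the top bin."""
    width = 180.0 / n_bins
    idx = np.floor((rel + 90.0) / width).astype(np.int64)
    idx[idx == n_bins] = n_bins - 1
    return idx


_BIN_CENTERS_10 = np.linspace(-90, 90, 11)[:-1] + 9.0


def _loo_curve(
    X: np.ndarray,
    bins: np.ndarray,
    i: int,
    cov_estimator: str,
    n_bins: int,
) -> Optional[np.ndarray]:
    """Tuning curve for held-out trial ``i`` given per-trial bin indices
    ``bins`` (already relative to trial i). None if any bin is empty."""
    n, k = X.shape
    train = np.ones(n, dtype=bool)
    train[i] = False
    tb = bins[train]
    counts = np.bincount(tb, minlength=n_bins)
    if np.any(counts == 0):
        return None
    M = np.zeros((n_bins, k))
    np.add.at(M, tb, X[train])
    M /= counts[:, None]
    diff = M - X[i]
    if cov_estimator == "identity":
        d = np.sqrt(np.sum(diff**2, axis=1))
    else:
        Rres = X[train] - M[tb]
        cov = shrinkage_covariance(Rres)
        try:
            c, low = linalg.cho_factor(cov)
        except np.linalg.LinAlgError:
            return None
        sol = linalg.cho_solve((c, low), diff.T)
        d = np.sqrt(np.maximum(np.sum(diff.T * sol, axis=0), 0.0))
    sims = -d
    return sims - sims.mean()


def tuning_curve_loo(
    features: np.ndarray,
    orientations: np.ndarray,
    held_out_trial: int,
    cov_estimator: str = "shrinkage",
    n_bins: int = 10,
) -> Optional[TuningCurve]:
    """Leave-one-trial-out tuning curve for a single held-out trial.

    Training trials are binned by their orientation relative to the held-out
    trial's orientation; the 10 Mahalanobis distances to the bin means are
    negated and mean-centered. Returns ``None`` (missing, logged) if any
    bin has no training trial.
    """
    X = np.asarray(features, dtype=float)
    ori = np.asarray(orientations, dtype=float)
    rel = relative_orientation(ori, ori[held_out_trial])
    bins = _bin_index(np.asarray(rel), n_bins)
    sims = _loo_curve(X, bins, held_out_trial, cov_estimator, n_bins)
    if sims is None:
        logger.debug("empty bin for held-out trial %d; curve missing", held_out_trial)
        return None
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    return TuningCurve(sims, (edges[:-1] + edges[1:]) / 2.0, edges)


def tuning_curves_loo_all(
    features: np.ndarray,
    orientations: np.ndarray,
    cov_estimator: str = "shrinkage",
    n_bins: int = 10,
    use_fast: bool = True,
) -> np.ndarray:
    """All leave-one-out tuning curves; (n_trials, n_bins) with NaN rows
    where a bin was empty. Uses the compiled fold loop when numba is
    available (identical results; cross-checked in the test suite)."""
    X = np.ascontiguousarray(features, dtype=float)
    ori = np.asarray(orientations, dtype=float)
    n = len(ori)
    rel = relative_orientation(ori[None, :], ori[:, None])  # rel[i, j] = ori_j vs ori_i
    bins = _bin_index(rel, n_bins)
    if use_fast:
        from ._loo_fast import HAVE_NUMBA, _loo_all_jit

        if HAVE_NUMBA:
            return _loo_all_jit(X, bins, n_bins, cov_estimator == "identity")
    out = np.full((n, n_bins), np.nan)
    for i in range(n):
        sims = _loo_curve(X, bins[i], i, cov_estimator, n_bins)
        if sims is not None:
            out[i] = sims
    return out


def decoding_evidence(curve) -> float:
    """Cosine projection of a tuning curve onto the 0° axis.

    Mean over bins of ``similarity * cos(2·bin_center)`` — the angle is
    doubled because orientation is 180°-periodic. Accepts a
    :class:`TuningCurve` or an array whose last axis is bins.
    """
    if isinstance(curve, TuningCurve):
        sims, centers = curve.similarities, curve.bin_centers
    else:
        sims = np.asarray(curve, dtype=float)
        n_bins = sims.shape[-1]
        edges = np.linspace(-90.0, 90.0, n_bins + 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
    w = np.cos(2.0 * np.deg2rad(centers))
    out = np.mean(sims * w, axis=-1)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Time-resolved decoding
# ---------------------------------------------------------------------------

def _align(epochs: EpochsSet, trials) -> "pd.DataFrame":
    import pandas as pd

    sub = trials.set_index("trial_id").loc[epochs.trial_ids].reset_index()
    return sub


def decode_timecourse(
    epochs: EpochsSet,
    trials,
    label: str,
    config: AnalysisConfig,
    t_indices: Optional[Sequence[int]] = None,
) -> EvidenceTimecourse:
    """Leave-one-trial-out decoding of ``label`` at every valid time index.

    Eligible trials are those with the label orientation available (for
    ``previous_target`` this drops first-in-block trials). PCA is fit per
    time point on all eligible trials jointly (set
    ``config.pca_per_fold=True`` for leakage-free fold-wise fitting).
    Evidence per participant is the mean over trials.
    """
    if label not in LABEL_COLUMNS:
        raise ConfigError(f"unknown label {label!r}")
    sub = _align(epochs, trials)
    ori_all = sub[LABEL_COLUMNS[label]].to_numpy(dtype=float)
    eligible = np.isfinite(ori_all)
    n_el = int(eligible.sum())
    if n_el == 0:
        raise ValueError(f"no eligible trials for label {label!r}")
    if n_el < 20:
        logger.warning("only %d eligible trials for label %s", n_el, label)
    logger.info("decode %s: %d/%d eligible trials", label, n_el, len(sub))
    ep = epochs.select_trials(eligible)
    ori = ori_all[eligible]

    w = config.window_samples
    valid = np.arange(w - 1, ep.n_times)
    if t_indices is not None:
        t_indices = np.asarray(t_indices, dtype=int)
        skipped = t_indices[~np.isin(t_indices, valid)]
        if len(skipped):
            logger.info("skipping %d time points truncated by the epoch edge", len(skipped))
        valid = t_indices[np.isin(t_indices, valid)]
    elif config.decim > 1:
        valid = valid[:: config.decim]

    n_bins = config.n_bins
    curves = np.full((ep.n_trials, len(valid), n_bins), np.nan)
    for j, t in enumerate(valid):
        F = build_features(ep, int(t), w)
        if config.pca_per_fold:
            rel = relative_orientation(ori[None, :], ori[:, None])
            bins = _bin_index(rel, n_bins)
            for i in range(ep.n_trials):
                train = np.ones(ep.n_trials, dtype=bool)
                train[i] = False
                red = PCAReducer(config.pca_variance).fit(F[train])
                Z = red.transform(F)
                sims = _loo_curve(Z, bins[i], i, config.cov_estimator, n_bins)
                if sims is not None:
                    curves[i, j] = sims
        else:
            Z, _ = reduce_dimensionality(F, config.pca_variance)
            curves[:, j] = tuning_curves_loo_all(Z, ori, config.cov_estimator, n_bins)

    ev_trial = decoding_evidence(curves)  # (n_trials, n_times)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(ev_trial, axis=0)
    return EvidenceTimecourse(
        values=values,
        times=ep.times[valid],
        lock_event=ep.lock_event,
        label=label,
        trial_ids=ep.trial_ids,
        evidence_per_trial=ev_trial,
        curves=curves,
    )


def response_lock(
    epochs: EpochsSet,
    trials,
    rt_bounds: tuple = (0.65, 11.85),
    span: tuple = (-2.0, 0.0),
) -> EpochsSet:
    """Re-epoch so that time 0 is the moment the report was submitted.

    Trials are excluded (and logged with reasons) when the RT is missing,
    outside ``rt_bounds``, or the requested span does not fit inside the
    original epoch. The new time axis is ``span[0] + i/sfreq`` (per-trial
    alignment is quantized to the nearest sample).
    """
    sub = _align(epochs, trials)
    rt = sub["rt"].to_numpy(dtype=float)
    n_out = int(round((span[1] - span[0]) * epochs.sfreq))
    if n_out < 1:
        raise ConfigError("response-locked span is empty")

    keep, starts, reasons = [], [], {"missing_rt": 0, "rt_out_of_bounds": 0, "span_outside_epoch": 0}
    for i in range(epochs.n_trials):
        if not np.isfinite(rt[i]):
            reasons["missing_rt"] += 1
            continue
        if rt[i] < rt_bounds[0] or rt[i] > rt_bounds[1]:
            reasons["rt_out_of_bounds"] += 1
            continue
        i0 = int(round((rt[i] + span[0] - epochs.times[0]) * epochs.sfreq))
        if i0 < 0 or i0 + n_out > epochs.n_times:
            reasons["span_outside_epoch"] += 1
            continue
        keep.append(i)
        starts.append(i0)
    logger.info(
        "response_lock: kept %d/%d trials (excluded: %s)",
        len(keep), epochs.n_trials, reasons,
    )
    if not keep:
        raise ValueError("no trials survive response locking")
    data = np.stack(
        [epochs.data[i, :, s : s + n_out] for i, s in zip(keep, starts)], axis=0
    )
    return EpochsSet(
        data=data,
        times=span[0] + np.arange(n_out) / epochs.sfreq,
        sfreq=epochs.sfreq,
        sensor_ids=epochs.sensor_ids,
        sensor_pos=epochs.sensor_pos,
        lock_event="response",
        trial_ids=epochs.trial_ids[keep],
    )


# ---------------------------------------------------------------------------
# Searchlight
# ---------------------------------------------------------------------------

def sensor_neighborhoods(sensor_pos: np.ndarray, k: int) -> np.ndarray:
    """For each sensor, the indices of itself plus its k-1 nearest
    neighbors (Euclidean on sensor positions, ties broken by sensor index)."""
    n = len(sensor_pos)
    if k > n:
        raise ConfigError(f"searchlight k={k} exceeds {n} sensors")
    d = np.linalg.norm(sensor_pos[:, None, :] - sensor_pos[None, :, :], axis=-1)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def searchlight_map(
    epochs: EpochsSet,
    trials,
    spec: dict,
    k: int = 48,
    config: Optional[AnalysisConfig] = None,
    t_indices: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-sensor map of decoding evidence or neural-bias index.

    ``spec`` is ``{"kind": "evidence", "label": ...}`` or
    ``{"kind": "bias", "inducer": ...}`` with an optional ``"window"``
    (seconds pair) over which the time course is averaged. For each sensor
    the full pipeline runs on the sensor plus its k-1 nearest neighbors.
    """
    from . import bias_analysis as ba

    config = config or AnalysisConfig()
    nb = sensor_neighborhoods(epochs.sensor_pos, k)
    window = spec.get("window")
    out = np.empty(epochs.n_sensors)
    for s in range(epochs.n_sensors):
        sub_ep = epochs.select_sensors(nb[s])
        if spec["kind"] == "evidence":
            res = decode_timecourse(sub_ep, trials, spec["label"], config, t_indices)
            vals, times = res.values, res.times
        elif spec["kind"] == "bias":
            res = decode_timecourse(sub_ep, trials, "target", config, t_indices)
            asym = ba.asymmetry_from_curves(res.curves, config)
            sub = _align(sub_ep, trials)
            cw, ccw, _ = ba.sort_by_inducer(sub, spec["inducer"])
            vals = ba.neural_bias_timecourse(asym, res.trial_ids, cw, ccw)
            times = res.times
        else:
            raise ConfigError(f"unknown searchlight kind {spec['kind']!r}")
        if window is not None:
            sel = (times >= window[0]) & (times < window[1])
            vals = vals[..., sel]
        out[s] = np.nanmean(vals)
    return out


def topography_correlation(map_a, map_b):
    """Pearson correlation (rho, p) between two per-sensor topographies."""
    rho, p = stats.pearsonr(
        np.asarray(map_a, dtype=float), np.asarray(map_b, dtype=float)
    )
    return float(rho), float(p)
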