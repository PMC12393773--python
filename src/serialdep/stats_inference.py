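"""Group-level inference: cluster-based permutation tests and windowed
one-sample t tests.

The cluster test takes per-participant time courses (paired designs enter
as per-participant differences), forms contiguous clusters of samples whose
one-sample t value exceeds the two-tailed threshold at ``cluster_alpha``,
and compares each cluster's mass (sum of t values) against a sign-flip null
of the maximum absolute cluster mass, pooling positive and negative
clusters (two-tailed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import ValidationError, logger

__all__ = ["ClusterResult", "cluster_permutation_test", "window_ttest"]


@dataclass
class ClusterResult:
    """Contiguous significant time spans with their masses and permutation
    p-values (p >= 1/(n_permutations+1) by construction)."""

    clusters: list  # dicts: t_start, t_end, mass, p
    n_permutations: int
    tail: str = "two"
    cluster_alpha: float = 0.05
    threshold: float = field(default=np.nan)

    def as_dict(self) -> dict:
        return {
            "clusters": [dict(c) for c in self.clusters],
            "n_permutations": self.n_permutations,
            "tail": self.tail,
            "cluster_alpha": self.cluster_alpha,
            "threshold": self.threshold,
        }


def _tvalues(mean: np.ndarray, sumsq: np.ndarray, n: int) -> np.ndarray:
    """One-sample t against 0 from per-column means and raw sums of squares
    (sums of squares are sign-flip invariant)."""
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def _clusters(t: np.ndarray, thr: float):
    """Contiguous runs of supra-threshold samples, signed. Yields
    (start, stop_exclusive, mass)."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * t > thr
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        stops = np.flatnonzero(~padded[1:] & padded[:-1])
        for a, b in zip(starts, stops):
            out.append((int(a), int(b), float(t[a:b].sum())))
    return sorted(out)


def _max_abs_mass(t: np.ndarray, thr: float) -> float:
    runs = _clusters(t, thr)
    return max((abs(m) for *_, m in runs), default=0.0)


def cluster_permutation_test(
    timecourses: np.ndarray,
    times: np.ndarray = None,
    n_perm: int = 100_000,
    cluster_alpha: float = 0.05,
    seed: int = None,
    chunk: int = 2048,
) -> ClusterResult:
    """Two-tailed cluster-based sign-flip permutation test against zero.

    ``timecourses`` is participants × time. The cluster-forming threshold
    is the two-tailed t quantile at ``cluster_alpha``; cluster mass is the
    sum of t values; the null records the maximum absolute cluster mass per
    permutation; ``p = (1 + #{null >= |mass|}) / (1 + n_perm)``.
    """
    X = np.asarray(timecourses, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least 2 participants of time courses")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in input time courses")
    if n_perm < 100:
        logger.warning("cluster test with only %d permutations", n_perm)
    n, T = X.shape
    if times is None:
        times = np.arange(T, dtype=float)
    times = np.asarray(times, dtype=float)

    thr = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    sumsq = np.sum(X**2, axis=0)
    t_obs = _tvalues(X.mean(axis=0), sumsq, n)
    observed = _clusters(t_obs, thr)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(c, n)) * 2.0 - 1.0
        means = signs @ X / n
        tmat = _tvalues(means, sumsq[None, :], n)
        for r in range(c):
            null[done + r] = _max_abs_mass(tmat[r], thr)
        done += c

    clusters = []
    for a, b, mass in observed:
        p = (1.0 + np.sum(null >= abs(mass))) / (1.0 + n_perm)
        clusters.append(
            {
                "t_start": float(times[a]),
                "t_end": float(times[b - 1]),
                "mass": mass,
                "p": float(p),
            }
        )
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        threshold=thr,
    )


def window_ttest(per_participant_values, mu: float = 0.0):
    """Two-tailed one-sample t test; returns ``(t, p, df)``.

    Degenerate zero-variance input returns t=0, p=1 when the mean equals
    ``mu`` (and ±inf, p=0 otherwise) instead of NaN.
    """
    x = np.asarray(per_participant_values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValidationError("t test needs at least 2 values")
    if np.ptp(x) == 0:
        if x[0] == mu:
            return 0.0, 1.0, n - 1
        return float(np.sign(x[0] - mu) * np.inf), 0.0, n - 1
    res = stats.ttest_1samp(x, mu)
    return float(res.statistic), float(res.pvalue), n - 1
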