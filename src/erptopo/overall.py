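"""Global corrections for multiple testing over time.

A per-time-point TANOVA yields a series of p-values of which some fraction
falls below threshold by chance alone.  Because neighbouring time points
are dependent to an unknown degree, a Bonferroni-style correction by the
number of tests would be overly conservative.  Instead, the observed
p-series is compared, as a whole, against p-series that are compatible with
the null hypothesis — and those come for free: every randomization run of
the TANOVA can itself be converted into a p-series by ranking it against
all *other* runs, exactly as the observed data are ranked against all runs.

Three summary statistics of a p-series are supported:

* ``count`` — the number of sub-threshold time points;
* ``duration`` — the longest contiguous sub-threshold period (ms), which
  additionally yields the shortest duration that would be significant,
  i.e. the "green line" that can be drawn over the TANOVA display;
* ``fisher`` — Fisher's combined statistic −2 Σ ln p over all time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tanova import NullDistribution, TanovaResult

__all__ = [
    "OverallResult",
    "null_p_matrix",
    "count_statistic",
    "duration_statistic",
    "fisher_statistic",
    "overall_test",
]

_KINDS = ("count", "duration", "fisher")


@dataclass
class OverallResult:
    effect: str
    statistic_kind: str
    observed: float
    null_samples: np.ndarray
    p: float
    theta: float
    duration_threshold_ms: float | None = None


def _count_ge_excluding_self(stats: np.ndarray) -> np.ndarray:
    """Per column: for each entry, how many *other* rows are >= it."""
    R = stats.shape[0]
    out = np.empty_like(stats, dtype=np.int64)
    order = np.sort(stats, axis=0)
    for t in range(stats.shape[1]):
        pos = np.searchsorted(order[:, t], stats[:, t], side="left")
        out[:, t] = R - pos - 1  # self is always counted in R - pos
    return out


def null_p_matrix(nd: NullDistribution, effect: str) -> np.ndarray:
    """p-series of every randomization run, ranked against the other runs.

    ``p[r, t] = (1 + #{s != r : stat_st >= stat_rt}) / n_runs`` — the same
    add-one convention the observed series uses against all runs, so the
    two are exchangeable under the null.
    """
    stats = nd.for_effect(effect)
    R = stats.shape[0]
    if R < 20:
        warnings.warn("fewer than 20 runs: null p-series are unstable",
                      RuntimeWarning, stacklevel=2)
    return (1.0 + _count_ge_excluding_self(stats)) / R


def observed_p_series(observed: np.ndarray, nd: NullDistribution,
                      effect: str) -> np.ndarray:
    """Observed statistics ranked against all runs (add-one)."""
    stats = nd.for_effect(effect)
    R = stats.shape[0]
    cnt = (stats >= observed[None, :]).sum(axis=0)
    return (1.0 + cnt) / (R + 1.0)


def count_statistic(p: np.ndarray, theta: float) -> int:
    """Number of time points with p below threshold."""
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    return int((np.asarray(p) < theta).sum())


def duration_statistic(p: np.ndarray, theta: float, dt: float) -> float:
    """Longest contiguous sub-threshold period, in ms."""
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    below = np.asarray(p) < theta
    longest = run = 0
    for b in below:
        run = run + 1 if b else 0
        longest = max(longest, run)
    return longest * dt


def _durations_matrix(p: np.ndarray, theta: float, dt: float) -> np.ndarray:
    """Longest sub-threshold run per row, vectorized over rows."""
    below = np.asarray(p) < theta
    R, T = below.shape
    run = np.zeros(R)
    longest = np.zeros(R)
    for t in range(T):
        run = np.where(below[:, t], run + 1, 0.0)
        longest = np.maximum(longest, run)
    return longest * dt


def fisher_statistic(p: np.ndarray) -> float:
    """Fisher's combined statistic −2 Σ ln p."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("Fisher's method requires all p > 0")
    return float(-2.0 * np.log(p).sum())


def overall_test(result: TanovaResult, effect: str, kind: str,
                 theta: float | None = None) -> OverallResult:
    """Test one summary statistic of the observed p-series for significance.

    The observed series is ranked against all runs, each run's null series
    against the other runs (leave-one-out), the chosen statistic is applied
    to all of them, and the overall p is the add-one fraction of null
    statistics at least as large as the observed one.  For ``duration`` the
    (1−theta)-level critical duration of the null is reported as well.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    if effect not in result.effects:
        raise ValueError(f"effect {effect!r} not in result {result.effects}")
    if theta is None:
        theta = result.config.p_threshold
    nd = result.null
    obs_p = observed_p_series(result.observed_for(effect), nd, effect)
    null_p = null_p_matrix(nd, effect)
    R = null_p.shape[0]
    duration_threshold = None
    if kind == "count":
        observed = float(count_statistic(obs_p, theta))
        null_samples = (null_p < theta).sum(axis=1).astype(float)
    elif kind == "duration":
        observed = duration_statistic(obs_p, theta, result.dt)
        null_samples = _durations_matrix(null_p, theta, result.dt)
        # shortest duration whose null exceedance probability is <= theta
        grid = result.dt * np.arange(1, null_p.shape[1] + 1)
        exceed = (1.0 + (null_samples[:, None] >= grid[None, :]).sum(axis=0)
                  ) / (R + 1.0)
        ok = np.nonzero(exceed <= theta)[0]
        duration_threshold = float(grid[ok[0]]) if ok.size else float("inf")
    else:
        observed = fisher_statistic(obs_p)
        null_samples = -2.0 * np.log(null_p).sum(axis=1)
    b = int((null_samples >= observed).sum())
    p = b / R if result.config.legacy_p else (1.0 + b) / (R + 1.0)
    return OverallResult(effect=effect, statistic_kind=kind,
                         observed=observed, null_samples=null_samples, p=p,
                         theta=theta,
                         duration_threshold_ms=duration_threshold)
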