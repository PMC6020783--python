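"""Topographic analysis of variance (TANOVA) and its GFP-test twin.

TANOVA tests, per time point, whether the grand-mean scalp maps of the
levels of an experimental factor differ more than chance would allow.  The
effect size is the root-mean-square deviation of the level-mean maps from
their common mean,

    dGFP = sqrt( Σ_i Σ_j (v̄_ij − v̄̄_j)² / n ),

summing over the c factor levels i and the n channels j — the multivariate
generalisation of "GFP of the difference map".  Its null distribution is
obtained by shuffling factor levels within subjects (and/or group labels
across subjects) and recomputing; the p-value is the add-one fraction of
permutation statistics at least as large as the observed one.

Because maps may differ purely in strength (quantitative effects) or in
spatial configuration (qualitative effects), each subject's maps can be
normalized to unit GFP before the TANOVA; the discarded scaling factor is
then tested separately by :func:`gfp_test`, which applies the identical
machinery to the scalar per-map GFP values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (EffectCellMeans, ErpDataset, average_reference, gfp,
                   normalize_by_gfp, window_to_samples)
from .design import Design, effect_deviations

__all__ = [
    "RandConfig",
    "NullDistribution",
    "TanovaResult",
    "dgfp",
    "tanova",
    "gfp_test",
    "window_average_test",
    "pca_projection",
]


@dataclass(frozen=True)
class RandConfig:
    """Shared settings for all randomization tests.

    5000 runs is the publication standard; 1000 is the recommended minimum
    for an accurate estimate of significance at the 5% level.  ``legacy_p``
    switches from the add-one convention (1+b)/(n+1), which guarantees
    p > 0, to the literal fraction b/n.
    """

    n_runs: int = 5000
    p_threshold: float = 0.05
    normalize: bool = False
    seed: int | None = None
    legacy_p: bool = False
    interaction: str = "residualized"

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class NullDistribution:
    """Permutation samples of the effect statistics.

    ``samples[e, r, t]`` is effect ``effects[e]``'s statistic in
    randomization run ``r`` at time point ``t``.  All effects share the
    same per-run shuffles, so the samples are reusable run-by-run by the
    overall statistics.
    """

    effects: tuple
    samples: np.ndarray  # (n_effects, n_runs, n_timepoints)

    @property
    def n_runs(self) -> int:
        return self.samples.shape[1]

    def for_effect(self, effect: str) -> np.ndarray:
        return self.samples[self.effects.index(effect)]


@dataclass
class TanovaResult:
    """Observed statistics, p-value series and the retained null."""

    effects: tuple
    times: np.ndarray
    observed: np.ndarray       # (n_effects, n_timepoints)
    p: np.ndarray              # (n_effects, n_timepoints)
    null: NullDistribution
    config: RandConfig
    dt: float
    statistic: str = "dgfp"

    def observed_for(self, effect: str) -> np.ndarray:
        return self.observed[self.effects.index(effect)]

    def p_for(self, effect: str) -> np.ndarray:
        return self.p[self.effects.index(effect)]


def dgfp(cm, n_channels: int | None = None):
    """Effect strength of a set of level-mean maps.

    Accepts an :class:`~erptopo.core.EffectCellMeans` (level means of shape
    ``(levels, time, channels)``, returning one value per time point) or a
    plain ``(levels, channels)`` array for a single time point (the overall
    mean is then the mean of the level means).
    """
    if isinstance(cm, EffectCellMeans):
        lm = np.asarray(cm.level_means, dtype=float)
        ov = np.expand_dims(np.asarray(cm.overall_mean, dtype=float), -3)
    else:
        lm = np.asarray(cm, dtype=float)
        if lm.ndim == 2:
            lm = lm[:, None, :]
        ov = lm.mean(axis=-3, keepdims=True)
    if lm.shape[-3] < 2:
        raise ValueError("dGFP requires at least 2 levels")
    n = n_channels if n_channels is not None else lm.shape[-1]
    out = np.sqrt(((lm - ov) ** 2).sum(axis=(-3, -1)) / n)
    return float(out[0]) if out.shape == (1,) else out


# ---------------------------------------------------------------------------
# randomization engine (shared by tanova, gfp_test, window tests, t-maps)
# ---------------------------------------------------------------------------


def _stat_from_dev(dev: np.ndarray, n_channels: int) -> np.ndarray:
    return np.sqrt((dev ** 2).sum(axis=(-3, -1)) / n_channels)


def randomization_test(data: np.ndarray, d: Design, cfg: RandConfig,
                       rng: np.random.Generator | None = None):
    """Core permutation loop on a (subjects, conditions, time, channels) array.

    Draws one shuffle per run — an independent uniform permutation of each
    subject's condition labels plus, when a between factor exists, a uniform
    permutation of the group labels — and evaluates every effect of the
    design on it.  Returns ``(observed, null)`` with shapes
    ``(n_effects, T)`` and ``(n_effects, n_runs, T)``.
    """
    S, K, T, C = data.shape
    effects = d.effects
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    observed = np.stack([
        _stat_from_dev(effect_deviations(data, d, e, None,
                                         cfg.interaction)[1], C)
        for e in effects])
    R = cfg.n_runs
    # all randomness drawn up front so results do not depend on chunking
    cond_keys = rng.random((R, S, K))
    cond_perms = np.argsort(cond_keys, axis=-1)
    subj_perms = None
    if d.has_between:
        subj_perms = np.argsort(rng.random((R, S)), axis=-1)
    null = np.empty((len(effects), R, T))
    chunk = max(1, int(5_000_000 // max(1, data.size)))
    scopes = {e: d.permutation_scope(e) for e in effects}
    for start in range(0, R, chunk):
        stop = min(start + chunk, R)
        rc = stop - start
        bdata = np.broadcast_to(data, (rc,) + data.shape)
        cache = {}

        def permuted(scope):
            if scope not in cache:
                arr = bdata
                if scope in ("between", "both"):
                    arr = np.take_along_axis(
                        arr, subj_perms[start:stop, :, None, None, None],
                        axis=1)
                if scope in ("within", "both"):
                    arr = np.take_along_axis(
                        arr, cond_perms[start:stop, :, :, None, None], axis=2)
                cache[scope] = arr
            return cache[scope]

        for ei, e in enumerate(effects):
            dev = effect_deviations(permuted(scopes[e]), d, e, None,
                                    cfg.interaction)[1]
            null[ei, start:stop] = _stat_from_dev(dev, C)
    return observed, null


def p_from_null(observed: np.ndarray, null: np.ndarray,
                legacy: bool = False) -> np.ndarray:
    """Add-one permutation p-values, ties counted as >= (conservative)."""
    b = (null >= observed[..., None, :]).sum(axis=-2)
    n = null.shape[-2]
    if legacy:
        return b / n
    return (1.0 + b) / (n + 1.0)


def _prepare(ds: ErpDataset, normalize: bool) -> np.ndarray:
    data = ds.data
    if not ds.is_average_referenced:
        data = average_reference(data)
    if normalize:
        data, _ = normalize_by_gfp(data, warn=False)
    return data


def tanova(ds: ErpDataset, d: Design, cfg: RandConfig = RandConfig()
           ) -> TanovaResult:
    """Per-time-point randomization test of topographic differences.

    With ``cfg.normalize`` each subject × condition map is divided by its
    GFP at every time point before averaging, so significant effects are
    attributable to changes in spatial configuration rather than overall
    strength.
    """
    data = _prepare(ds, cfg.normalize)
    observed, null = randomization_test(data, d, cfg)
    return TanovaResult(
        effects=d.effects, times=ds.times, observed=observed,
        p=p_from_null(observed, null, cfg.legacy_p),
        null=NullDistribution(d.effects, null), config=cfg, dt=ds.dt,
        statistic="dgfp")


def gfp_test(ds: ErpDataset, d: Design, cfg: RandConfig = RandConfig()
             ) -> TanovaResult:
    """Randomization test on map strength (GFP), parallel to the TANOVA.

    The per-map GFP replaces the map as a single-"channel" observation, so
    the statistic is sqrt( Σ_i (ḡ_i − ḡ)² ) over the level means of the
    per-subject GFP values, with the identical permutation scheme.  Maps
    are never normalized here — the GFP is exactly what normalization
    removes.
    """
    data = _prepare(ds, False)
    gdata = gfp(data)[..., None]  # (S, K, T, 1)
    cfg = replace(cfg, normalize=False)
    observed, null = randomization_test(gdata, d, cfg)
    return TanovaResult(
        effects=d.effects, times=ds.times, observed=observed,
        p=p_from_null(observed, null, cfg.legacy_p),
        null=NullDistribution(d.effects, null), config=cfg, dt=ds.dt,
        statistic="gfp")


def window_average_test(ds: ErpDataset, d: Design, window,
                        cfg: RandConfig = RandConfig(),
                        statistic: str = "dgfp") -> TanovaResult:
    """TANOVA (or GFP test) on maps averaged across one time window.

    The window is inclusive in ms; maps are averaged per subject and
    condition before the identical per-time-point test, yielding a single
    p per effect.  With the same seed and a single-sample window this
    reproduces that sample's per-time-point p exactly, because the
    permutation stream does not depend on the number of time points.
    """
    first, last = window_to_samples(window, ds.dt, ds.t0, ds.n_timepoints)
    avg = ds.data[:, :, first:last + 1].mean(axis=2, keepdims=True)
    wds = replace(ds, data=avg, t0=ds.t0 + first * ds.dt)
    if statistic == "gfp":
        return gfp_test(wds, d, cfg)
    return tanova(wds, d, cfg)


def pca_projection(maps: np.ndarray):
    """Project a set of mean maps onto their first two principal components.

    Returns ``(scores, components)``: per-map 2-D coordinates for the
    state-space scatter display, and the two eigenvector maps shown on its
    axes.  Distances in the projection never exceed the corresponding
    full-space distances.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need at least two maps of shape (n_maps, "
                         "n_channels)")
    centered = maps - maps.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(2, vt.shape[0])
    scores = np.zeros((maps.shape[0], 2))
    components = np.zeros((2, maps.shape[1]))
    scores[:, :k] = u[:, :k] * s[:k]
    components[:k] = vt[:k]
    return scores, components
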