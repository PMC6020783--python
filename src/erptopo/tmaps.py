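"""Post-hoc channel-wise t-maps on window-averaged contrasts.

After a TANOVA has localized an effect in time, a t-map shows *where on the
scalp* two selections of the data differ: per channel, the mean difference
of the window-averaged maps divided by its standard error — a local index
of the signal-to-noise ratio.  The companion TANOVA p of the identical
contrast is computed alongside, so the global and local views always refer
to the same data and the same permutation seed.

A selection names conditions (averaged together), an optional subject
subset (e.g. one group), and an optional baseline selection of conditions
whose window average is subtracted.  The test type is auto-detected:
selections over the same subjects give a paired t (df = n − 1), disjoint
subject sets give a two-sample t with pooled variance (df = n₁ + n₂ − 2).
The subtraction direction is explicit: ``tmap(a, b, ...)`` tests a − b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ErpDataset, average_reference, window_to_samples
from .design import define_design
from .tanova import RandConfig, p_from_null, randomization_test

__all__ = ["Selection", "TMapResult", "tmap"]


@dataclass(frozen=True)
class Selection:
    """One side of a contrast: conditions, optional subjects and baseline."""

    conditions: tuple
    subjects: tuple | None = None
    baseline: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "conditions",
                           tuple(str(c) for c in self.conditions))
        if self.subjects is not None:
            object.__setattr__(self, "subjects",
                               tuple(str(s) for s in self.subjects))
        if self.baseline is not None:
            object.__setattr__(self, "baseline",
                               tuple(str(c) for c in self.baseline))


@dataclass
class TMapResult:
    t_values: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    contrast_p: float
    df: int
    paired: bool
    channel_labels: tuple = ()


def _window_maps(ds: ErpDataset, sel: Selection, first: int, last: int):
    """Per-subject window-averaged map of one selection: (n_subjects, C)."""
    if sel.subjects is None:
        sidx = np.arange(ds.n_subjects)
    else:
        sidx = np.asarray([ds.subject_ids.index(s) for s in sel.subjects])
    cidx = np.asarray([ds.condition_tags.index(c) for c in sel.conditions])
    maps = ds.data[np.ix_(sidx, cidx)][:, :, first:last + 1].mean(axis=(1, 2))
    if sel.baseline:
        bidx = np.asarray([ds.condition_tags.index(c) for c in sel.baseline])
        maps = maps - ds.data[np.ix_(sidx, bidx)][:, :, first:last + 1] \
            .mean(axis=(1, 2))
    return maps, tuple(ds.subject_ids[i] for i in sidx)


def tmap(ds: ErpDataset, a: Selection, b: Selection, window,
         cfg: RandConfig = RandConfig(), paired: str | bool = "auto"
         ) -> TMapResult:
    """Channel-wise t statistics for the contrast a − b over a time window.

    Channels with zero variance of the differences are reported as ±inf
    sentinels (0 when the mean difference is also zero) with a warning, so
    the output stays rectangular.
    """
    first, last = window_to_samples(window, ds.dt, ds.t0, ds.n_timepoints)
    maps_a, subj_a = _window_maps(ds, a, first, last)
    maps_b, subj_b = _window_maps(ds, b, first, last)
    if paired == "auto":
        paired = set(subj_a) == set(subj_b)
    paired = bool(paired)
    if paired:
        if subj_a != subj_b:  # align subject order
            order = [subj_b.index(s) for s in subj_a]
            maps_b = maps_b[order]
        n = maps_a.shape[0]
        if n < 2:
            raise ValueError("paired t-map requires at least 2 subjects")
        diff = maps_a - maps_b
        mean = diff.mean(axis=0)
        sd = diff.std(axis=0, ddof=1)
        df = n - 1
        se = sd / np.sqrt(n)
    else:
        n1, n2 = maps_a.shape[0], maps_b.shape[0]
        if min(n1, n2) < 2:
            raise ValueError("unpaired t-map requires at least 2 subjects "
                             "per group")
        mean = maps_a.mean(axis=0) - maps_b.mean(axis=0)
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * maps_a.var(axis=0, ddof=1)
                  + (n2 - 1) * maps_b.var(axis=0, ddof=1)) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    zero = se == 0
    if np.any(zero):
        t = np.where(zero & (mean == 0), 0.0,
                     np.where(zero, np.sign(mean) * np.inf, t))
        warnings.warn(f"{int(zero.sum())} channel(s) with zero variance: "
                      "t reported as 0/±inf sentinel", RuntimeWarning,
                      stacklevel=2)
    contrast_p = _contrast_p(maps_a, maps_b, paired, cfg)
    labels = ds.montage.labels if ds.montage is not None else ()
    return TMapResult(t_values=t, mean_a=maps_a.mean(axis=0),
                      mean_b=maps_b.mean(axis=0), contrast_p=contrast_p,
                      df=df, paired=paired, channel_labels=labels)


def _contrast_p(maps_a, maps_b, paired: bool, cfg: RandConfig) -> float:
    """TANOVA p of the same two-selection contrast, same seed.

    Paired: within-subject swapping of the two selections is equivalent to
    flipping the sign of each subject's difference map, and the effect
    statistic is the GFP of the mean difference map — this formulation is
    exactly antisymmetric, so the p is identical under order swap.
    """
    maps_a = average_reference(maps_a)
    maps_b = average_reference(maps_b)
    rng = np.random.default_rng(cfg.seed)
    if paired:
        diff = maps_a - maps_b
        observed = diff.mean(axis=0).std()
        signs = np.where(rng.random((cfg.n_runs, diff.shape[0])) < 0.5,
                         -1.0, 1.0)
        null = (signs[:, :, None] * diff).mean(axis=1).std(axis=-1)
        b = int((null >= observed).sum())
        return b / cfg.n_runs if cfg.legacy_p \
            else (1.0 + b) / (cfg.n_runs + 1.0)
    # unpaired: shuffle group labels; a canonical group order makes the
    # result independent of which selection is called "a"
    groups = [(0, m) for m in maps_a] + [(1, m) for m in maps_b]
    key_a = (maps_a.shape[0], maps_a.sum())
    key_b = (maps_b.shape[0], maps_b.sum())
    if key_b < key_a:
        groups = [(1 - g, m) for g, m in groups]
    data = np.stack([m for _, m in groups])[:, None, None, :]
    d = define_design({}, ["all"], groups=[g for g, _ in groups])
    observed, null = randomization_test(data, d, cfg, rng=rng)
    return float(p_from_null(observed, null, cfg.legacy_p)[0, 0])
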