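"""Microstate analysis: clustering, labeling, quantifiers and statistics.

Microstate analysis decomposes grand-mean ERP map series into a small set
of template maps such that every time point belongs to exactly one
template; a *microstate* is a maximal contiguous period assigned to the
same template.  Unlike PCA/ICA decompositions, temporal overlap between
components is excluded by construction, which makes onsets, offsets and
durations of components sharply defined and therefore testable.

Two clustering algorithms are provided as scikit-learn style estimators:
a modified k-means (best-of-restarts, assignment by spatial correlation)
and the deterministic atomize-and-agglomerate hierarchical clustering
(AAHC), which starts from one cluster per map and repeatedly disbands the
cluster contributing least explained variance, reassigning its members to
the best-fitting survivors.

Spatial correlation between maps is the Pearson correlation across
channels; with ``polarity="ignore"`` its absolute value is used, treating
a sign-flipped field as the same generator configuration.  Explained
variance is GFP²-weighted:  EV = Σ_t (GFP_t · r_t)² / Σ_t GFP_t², where
r_t is the correlation of the map at t with its assigned template.

Statistics: each microstate class is quantified per design cell
(onset, offset, duration, area under the GFP curve, GFP-weighted center
of gravity, mean GFP), and the variance of each quantifier across cells
is tested against shuffled-design permutations of the same quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .core import ErpDataset, average_reference, window_to_samples
from .design import Design, effect_deviations, permute_design
from .tanova import RandConfig

__all__ = [
    "MicrostateKMeans",
    "MicrostateAAHC",
    "cluster_kmeans",
    "cluster_aahc",
    "assign",
    "smooth_labels",
    "explained_variance",
    "spatial_correlation",
    "microstate_quantifiers",
    "CrossValidationCurve",
    "cross_validate_k",
    "microstate_test",
    "cell_grand_means",
]

QUANTIFIERS = ("onset", "offset", "duration", "auc", "cog", "mean_gfp")
_TIMING = ("onset", "offset", "cog")


# ---------------------------------------------------------------------------
# map algebra helpers
# ---------------------------------------------------------------------------


def _unit_l2(maps: np.ndarray) -> np.ndarray:
    """Average-reference and L2-normalize maps; zero maps stay zero."""
    c = average_reference(np.asarray(maps, dtype=float))
    norm = np.linalg.norm(c, axis=-1, keepdims=True)
    return np.divide(c, norm, out=np.zeros_like(c), where=norm > 0)


def spatial_correlation(maps: np.ndarray, templates: np.ndarray
                        ) -> np.ndarray:
    """Pearson correlation across channels of each map with each template."""
    return _unit_l2(np.atleast_2d(maps)) @ _unit_l2(
        np.atleast_2d(templates)).T


def _best_labels(corr: np.ndarray, polarity: str) -> np.ndarray:
    c = np.abs(corr) if polarity == "ignore" else corr
    return np.argmax(c, axis=1)  # ties -> lowest index


def _ev_from_corr(c_maps: np.ndarray, corr: np.ndarray,
                  labels: np.ndarray) -> float:
    """EV = Σ (c·u)² / Σ ||c||² using centered maps and their best corr."""
    total = float((c_maps ** 2).sum())
    if total == 0:
        raise ValueError("explained variance undefined for all-zero data")
    norms2 = (c_maps ** 2).sum(axis=1)
    picked = corr[np.arange(corr.shape[0]), labels]
    return float((norms2 * picked ** 2).sum() / total)


def _template_from_members(c_members: np.ndarray, polarity: str
                           ) -> np.ndarray:
    """Cluster center as a unit-L2 map.

    Polarity-sensitive: normalized sum of the (centered) member maps, so
    stronger maps weigh more.  Polarity-ignore: first right singular
    vector, which maximizes Σ (c·w)² regardless of sign.
    """
    if polarity == "ignore":
        _, _, vt = np.linalg.svd(c_members, full_matrices=False)
        w = vt[0]
    else:
        w = c_members.sum(axis=0)
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros(c_members.shape[1])
    return w / norm


def _as_unit_gfp(w_unit_l2: np.ndarray) -> np.ndarray:
    """Convert unit-L2 templates to unit-GFP scaling for display/export."""
    return w_unit_l2 * np.sqrt(w_unit_l2.shape[-1])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _MicrostateBase(ClusterMixin, BaseEstimator):
    """Shared assignment/EV machinery for microstate clusterers."""

    def _check_fitted(self):
        if not hasattr(self, "templates_"):
            raise ValueError("estimator is not fitted")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Assign each map to the best-fitting template.

        Zero maps correlate with nothing and get label 0 with a warning.
        """
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        u = _unit_l2(X)
        if np.any(np.linalg.norm(u, axis=1) == 0):
            warnings.warn("zero map(s) assigned to class 0", RuntimeWarning,
                          stacklevel=2)
        corr = u @ self._w.T
        return _best_labels(corr, self.polarity)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _finalize(self, X, w, labels):
        c = average_reference(np.asarray(X, dtype=float))
        corr = _unit_l2(c) @ w.T
        self._w = w
        self.templates_ = _as_unit_gfp(w)
        self.labels_ = labels
        self.explained_variance_ = _ev_from_corr(c, corr, labels)
        return self


class MicrostateKMeans(_MicrostateBase):
    """Modified k-means microstate clustering.

    Parameters
    ----------
    n_states : int
        Number of template maps (k ≥ 2).
    n_init : int
        Random restarts; the model with the highest explained variance
        wins.
    tol : float
        Convergence when the explained-variance improvement of an
        iteration falls below this value.
    polarity : {"sensitive", "ignore"}
        Whether a sign-flipped map counts as the same state.  For ERPs the
        default is polarity-sensitive: an inverted field is a different
        component.
    init_templates : ndarray or None
        Optional extra initialization (e.g. a warm start from a smaller
        model); padded with the worst-fit map if it has fewer than
        ``n_states`` rows.

    Attributes
    ----------
    templates_ : ndarray of shape (n_states, n_channels)
        Unit-GFP template maps.
    labels_ : ndarray
        Training-map assignment.
    explained_variance_ : float
    """

    def __init__(self, n_states=4, n_init=20, max_iter=200, tol=1e-7,
                 polarity="sensitive", random_state=None,
                 init_templates=None):
        self.n_states = n_states
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.polarity = polarity
        self.random_state = random_state
        self.init_templates = init_templates

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k = int(self.n_states)
        if k < 2:
            raise ValueError("n_states must be >= 2")
        c = average_reference(X)
        u = _unit_l2(c)
        nonzero = np.nonzero(np.linalg.norm(u, axis=1) > 0)[0]
        distinct = np.unique(np.round(u[nonzero], 12), axis=0).shape[0]
        if distinct < k:
            raise ValueError(
                f"k={k} exceeds the number of distinct non-degenerate maps "
                f"({distinct})")
        rng = np.random.default_rng(self.random_state)
        inits = [u[rng.choice(nonzero, size=k, replace=False)]
                 for _ in range(int(self.n_init))]
        if self.init_templates is not None:
            inits.append(self._pad_init(
                _unit_l2(np.asarray(self.init_templates, float)), u, c, k))
        best = (-1.0, None, None)
        for w0 in inits:
            w, labels, ev = self._run(c, u, w0.copy())
            if ev > best[0]:
                best = (ev, w, labels)
        return self._finalize(X, best[1], best[2])

    def _pad_init(self, w0, u, c, k):
        while w0.shape[0] < k:
            corr = u @ w0.T
            best = np.max(np.abs(corr) if self.polarity == "ignore"
                          else corr, axis=1)
            resid = (c ** 2).sum(axis=1) * (1.0 - np.clip(best, -1, 1) ** 2)
            w0 = np.vstack([w0, u[int(np.argmax(resid))]])
        return w0[:k]

    def _run(self, c, u, w):
        prev_ev = -np.inf
        labels = None
        for _ in range(int(self.max_iter)):
            corr = u @ w.T
            labels = _best_labels(corr, self.polarity)
            for j in range(w.shape[0]):
                members = labels == j
                if not members.any():
                    # re-seed an empty cluster on the worst-fit map
                    best = np.max(np.abs(corr) if self.polarity == "ignore"
                                  else corr, axis=1)
                    resid = ((c ** 2).sum(axis=1)
                             * (1.0 - np.clip(best, -1, 1) ** 2))
                    w[j] = u[int(np.argmax(resid))]
                else:
                    w[j] = _template_from_members(c[members], self.polarity)
            corr = u @ w.T
            labels = _best_labels(corr, self.polarity)
            ev = _ev_from_corr(c, corr, labels)
            if ev - prev_ev < self.tol:
                prev_ev = ev
                break
            prev_ev = ev
        return w, labels, prev_ev


class MicrostateAAHC(_MicrostateBase):
    """Atomize-and-agglomerate hierarchical clustering (deterministic).

    Every map starts as its own cluster; the cluster contributing least to
    the global explained variance is repeatedly disbanded ("atomized") and
    its member maps are reassigned each to the best-fitting surviving
    cluster, until ``n_states`` clusters remain.
    """

    def __init__(self, n_states=4, polarity="sensitive"):
        self.n_states = n_states
        self.polarity = polarity

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k = int(self.n_states)
        if k < 2:
            raise ValueError("n_states must be >= 2")
        c = average_reference(X)
        u = _unit_l2(c)
        nonzero = np.linalg.norm(u, axis=1) > 0
        if int(np.unique(np.round(u[nonzero], 12), axis=0).shape[0]) < k:
            raise ValueError("k exceeds the number of distinct maps")
        members = [[i] for i in np.nonzero(nonzero)[0]]
        w = [u[m[0]].copy() for m in members]
        history = {}
        while len(members) >= k:
            history[len(members)] = ([list(m) for m in members],
                                     np.array(w))
            if len(members) == k:
                break
            contrib = np.array([
                float(((c[m] @ wj) ** 2).sum())
                for m, wj in zip(members, w)])
            worst = int(np.argmin(contrib))
            orphans = members.pop(worst)
            w.pop(worst)
            warr = np.array(w)
            corr = u[orphans] @ warr.T
            target = _best_labels(corr, self.polarity)
            for o, tj in zip(orphans, target):
                members[int(tj)].append(int(o))
            for j in set(int(t) for t in target):
                w[j] = _template_from_members(c[members[j]], self.polarity)
        final_members, final_w = history[k]
        warr = np.array([w_ for w_ in final_w])
        labels = _best_labels(u @ warr.T, self.polarity)
        return self._finalize(X, warr, labels)


def cluster_kmeans(maps, k, restarts=20, rng=None,
                   polarity="sensitive") -> MicrostateKMeans:
    """Functional wrapper around :class:`MicrostateKMeans`."""
    seed = rng if isinstance(rng, (int, np.integer, type(None))) else \
        int(rng.integers(2 ** 31))
    return MicrostateKMeans(n_states=k, n_init=restarts, random_state=seed,
                            polarity=polarity).fit(np.asarray(maps))


def cluster_aahc(maps, k, polarity="sensitive") -> MicrostateAAHC:
    """Functional wrapper around :class:`MicrostateAAHC`."""
    return MicrostateAAHC(n_states=k, polarity=polarity).fit(
        np.asarray(maps))


def assign(maps, model) -> np.ndarray:
    """Label each map with its best-fitting template (see ``predict``)."""
    return model.predict(np.asarray(maps))


def explained_variance(maps, model, labels) -> float:
    """GFP²-weighted explained variance of a labeling under a model."""
    c = average_reference(np.asarray(maps, dtype=float))
    corr = _unit_l2(c) @ model._w.T
    return _ev_from_corr(c, corr, np.asarray(labels))


# ---------------------------------------------------------------------------
# label smoothing
# ---------------------------------------------------------------------------


def _segments(labels: np.ndarray):
    """Maximal runs of equal labels as (start, stop_inclusive, label)."""
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((start, i - 1, int(labels[start])))
            start = i
    return segs


def smooth_labels(labels: np.ndarray, maps: np.ndarray, model,
                  min_duration_ms: float, dt: float) -> np.ndarray:
    """Dissolve microstate segments shorter than a minimum duration.

    The shortest offending segment (leftmost on ties) is merged into its
    temporal neighbours: its time points are split at the boundary that
    maximizes the summed correlation with the left and right neighbour
    templates (boundary segments join their only neighbour).  Iterates
    until no short segment remains or a single segment covers the series.
    """
    labels = np.asarray(labels).copy()
    min_samples = max(1, int(round(min_duration_ms / dt)))
    corr = spatial_correlation(maps, model._w * np.sqrt(maps.shape[-1]))
    if model.polarity == "ignore":
        corr = np.abs(corr)
    while True:
        segs = _segments(labels)
        if len(segs) <= 1:
            break
        short = [(e - s + 1, i) for i, (s, e, _) in enumerate(segs)
                 if e - s + 1 < min_samples]
        if not short:
            break
        _, si = min(short)
        s, e, _ = segs[si]
        left = segs[si - 1][2] if si > 0 else None
        right = segs[si + 1][2] if si < len(segs) - 1 else None
        if left is None:
            labels[s:e + 1] = right
        elif right is None:
            labels[s:e + 1] = left
        else:
            cl = corr[s:e + 1, left]
            cr = corr[s:e + 1, right]
            m = e - s + 1
            # split k: points [0, k) go left, [k, m) go right
            gains = [cl[:k].sum() + cr[k:].sum() for k in range(m + 1)]
            k = int(np.argmax(gains))
            labels[s:s + k] = left
            labels[s + k:e + 1] = right
    return labels


# ---------------------------------------------------------------------------
# quantifiers
# ---------------------------------------------------------------------------


def microstate_quantifiers(labels: np.ndarray, gfp_series: np.ndarray,
                           times: np.ndarray, n_states: int) -> pd.DataFrame:
    """Per-class microstate quantifiers over one labeled map series.

    All samples assigned to a class within the analyzed window pool
    together (a class split into several segments is quantified as one).
    Conventions: onset/offset are the times of the first/last assigned
    sample; duration = sample count × dt; auc = Σ GFP·dt (µV·ms);
    cog = Σ t·GFP / Σ GFP; mean_gfp = mean GFP over assigned samples.
    Absent classes have ``present=False`` and NaN quantifiers.
    """
    labels = np.asarray(labels)
    gfp_series = np.asarray(gfp_series, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    rows = []
    for k in range(n_states):
        sel = labels == k
        if not sel.any():
            rows.append(dict(state=k, present=False, onset=np.nan,
                             offset=np.nan, duration=0.0, auc=0.0,
                             cog=np.nan, mean_gfp=0.0))
            continue
        t = times[sel]
        g = gfp_series[sel]
        gsum = g.sum()
        rows.append(dict(
            state=k, present=True, onset=float(t[0]), offset=float(t[-1]),
            duration=float(sel.sum() * dt), auc=float(gsum * dt),
            cog=float((t * g).sum() / gsum) if gsum > 0 else float(t.mean()),
            mean_gfp=float(g.mean())))
    return pd.DataFrame(rows).set_index("state")


# ---------------------------------------------------------------------------
# cross-validation of the number of classes
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationCurve:
    k_values: tuple
    learning_ev: np.ndarray         # mean over splits
    test_ev: np.ndarray
    n_splits: int
    per_split_learning: np.ndarray = field(default=None, repr=False)
    per_split_test: np.ndarray = field(default=None, repr=False)


def cell_grand_means(ds: ErpDataset, d: Design | None = None) -> np.ndarray:
    """Group × condition grand-mean map series, stacked as (cells, T, C)."""
    data = ds.data
    if not ds.is_average_referenced:
        data = average_reference(data)
    if d is not None and d.has_between:
        gi = d.group_index()
        cells = [data[gi == g].mean(axis=0) for g in range(gi.max() + 1)]
        out = np.concatenate(cells, axis=0)
    else:
        out = data.mean(axis=0)
    return out  # (n_cells, T, C)


def cross_validate_k(ds: ErpDataset, d: Design | None, k_range,
                     split_fraction: float = 0.5, n_splits: int = 10,
                     algorithm: str = "kmeans", rng=None,
                     n_init: int = 10) -> CrossValidationCurve:
    """Choose the number of microstate classes by split-half prediction.

    Subjects are repeatedly split into a learning and a test set; models
    with increasing k are fitted on the learning-set grand means and
    projected onto the test-set grand means (best-fit re-assignment).  The
    learning-set explained variance grows with every class added; the
    test-set curve plateaus when additional classes stop generalizing —
    the beginning of the plateau marks the preferred k.
    """
    if ds.n_subjects < 4:
        raise ValueError("cross-validation requires at least 4 subjects")
    k_values = tuple(int(k) for k in k_range)
    rng = np.random.default_rng(rng)
    n_learn = int(round(split_fraction * ds.n_subjects))
    if min(n_learn, ds.n_subjects - n_learn) < 2:
        raise ValueError("split leaves fewer than 2 subjects on one side")
    learn_ev = np.empty((n_splits, len(k_values)))
    test_ev = np.empty((n_splits, len(k_values)))
    for split in range(n_splits):
        order = rng.permutation(ds.n_subjects)
        learn_idx, test_idx = order[:n_learn], order[n_learn:]
        sub = lambda idx: ErpDataset(
            ds.data[idx], tuple(ds.subject_ids[i] for i in idx),
            ds.condition_tags, dt=ds.dt, t0=ds.t0,
            is_average_referenced=ds.is_average_referenced)
        d_learn = _subset_design(d, learn_idx)
        d_test = _subset_design(d, test_idx)
        learn_maps = cell_grand_means(sub(learn_idx), d_learn)
        test_maps = cell_grand_means(sub(test_idx), d_test)
        lm = learn_maps.reshape(-1, learn_maps.shape[-1])
        tm = test_maps.reshape(-1, test_maps.shape[-1])
        prev = None
        for ki, k in enumerate(k_values):
            if algorithm == "kmeans":
                model = MicrostateKMeans(
                    n_states=k, n_init=n_init,
                    random_state=int(rng.integers(2 ** 31)),
                    init_templates=prev).fit(lm)
                prev = model.templates_
            elif algorithm == "aahc":
                model = MicrostateAAHC(n_states=k).fit(lm)
            else:
                raise ValueError(f"unknown algorithm {algorithm!r}")
            learn_ev[split, ki] = model.explained_variance_
            test_ev[split, ki] = explained_variance(tm, model,
                                                    model.predict(tm))
    return CrossValidationCurve(
        k_values=k_values, learning_ev=learn_ev.mean(axis=0),
        test_ev=test_ev.mean(axis=0), n_splits=n_splits,
        per_split_learning=learn_ev, per_split_test=test_ev)


def _subset_design(d: Design | None, idx) -> Design | None:
    if d is None or not d.has_between:
        return d
    from dataclasses import replace as _replace
    return _replace(d, groups=tuple(d.groups[i] for i in idx))


# ---------------------------------------------------------------------------
# quantifier randomization statistics
# ---------------------------------------------------------------------------


def _cell_quantifiers(cell_maps: np.ndarray, model, times, dt,
                      min_duration_ms: float):
    """Quantifier table per cell of one effect: (L, n_states, n_quant)."""
    k = model.templates_.shape[0]
    out = np.empty((cell_maps.shape[0], k, len(QUANTIFIERS)))
    present = np.empty((cell_maps.shape[0], k), dtype=bool)
    for li, maps in enumerate(cell_maps):
        labels = model.predict(maps)
        if min_duration_ms > 0:
            labels = smooth_labels(labels, maps, model, min_duration_ms, dt)
        g = average_reference(maps).std(axis=-1)
        q = microstate_quantifiers(labels, g, times, k)
        out[li] = q[list(QUANTIFIERS)].to_numpy()
        present[li] = q["present"].to_numpy()
    return out, present


def _variances(q: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Across-cell variance per (state, quantifier), absent-class policy.

    Global quantifiers (duration, auc, mean_gfp) of an absent class count
    as 0; timing quantifiers (onset, offset, cog) are computed over the
    cells where the class is present, and are 0 when fewer than two cells
    have it.
    """
    L, K, Q = q.shape
    out = np.zeros((K, Q))
    for qi, name in enumerate(QUANTIFIERS):
        vals = q[:, :, qi]
        if name in _TIMING:
            for k in range(K):
                pres = present[:, k]
                out[k, qi] = vals[pres, k].var() if pres.sum() >= 2 else 0.0
        else:
            out[:, qi] = np.nan_to_num(vals).var(axis=0)
    return out


def microstate_test(ds: ErpDataset, d: Design, model, window=None,
                    cfg: RandConfig = RandConfig(),
                    min_duration_ms: float | None = None) -> pd.DataFrame:
    """Randomization test of microstate quantifiers across design cells.

    The fitted template model stays fixed; per effect, the grand-mean map
    series of every factor level (or cell/group) is labeled, smoothed and
    quantified, and the across-cell variance of each quantifier of each
    class is the observed statistic.  The null repeats this after shuffling
    condition labels within subjects (and group labels across subjects).

    Returns a tidy frame with one row per (effect, state, quantifier):
    ``observed_variance``, ``p``, ``n_present`` (cells containing the class
    in the observed data) and ``testable``.
    """
    if min_duration_ms is None:
        min_duration_ms = 3 * ds.dt
    data = ds.data
    if not ds.is_average_referenced:
        data = average_reference(data)
    if window is not None:
        first, last = window_to_samples(window, ds.dt, ds.t0,
                                        ds.n_timepoints)
        data = data[:, :, first:last + 1]
        times = ds.times[first:last + 1]
    else:
        times = ds.times
    effects = d.effects
    scope = "both" if d.has_between else "within"
    rng = np.random.default_rng(cfg.seed)
    k = model.templates_.shape[0]

    def all_effect_variances(assignment):
        obs = {}
        pres = {}
        for e in effects:
            cells = effect_deviations(data, d, e, assignment,
                                      cfg.interaction)[0]
            q, p = _cell_quantifiers(cells, model, times, ds.dt,
                                     min_duration_ms)
            obs[e] = _variances(q, p)
            pres[e] = p
        return obs, pres

    observed, present = all_effect_variances(None)
    exceed = {e: np.zeros((k, len(QUANTIFIERS))) for e in effects}
    for _ in range(cfg.n_runs):
        assignment = permute_design(d, rng, scope, n_subjects=ds.n_subjects)
        null, _ = all_effect_variances(assignment)
        for e in effects:
            exceed[e] += null[e] >= observed[e]
    rows = []
    for e in effects:
        n_present = present[e].sum(axis=0)
        for ki in range(k):
            for qi, qname in enumerate(QUANTIFIERS):
                b = exceed[e][ki, qi]
                p = (b / cfg.n_runs if cfg.legacy_p
                     else (1.0 + b) / (cfg.n_runs + 1.0))
                rows.append(dict(
                    effect=e, state=ki, quantifier=qname,
                    observed_variance=observed[e][ki, qi], p=p,
                    n_present=int(n_present[ki]),
                    testable=bool(n_present[ki] > 0)))
    return pd.DataFrame(rows)
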