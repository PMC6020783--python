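"""Data inspection, preprocessing and MDS-based outlier screening.

Outlier screening works on whole subjects: all channels, time points and
conditions of a subject are flattened into one vector, the subject × subject
Pearson correlation matrix is converted to chord distances
d = sqrt(2(1 − r)), and classical (Torgerson) multidimensional scaling
embeds the subjects in the plane, with the origin at the mean of the data.
Subjects far from the center resemble the rest of the sample least.

An advisory auto-select flags candidate outliers with the classic
single-outlier test on the maximum Mahalanobis distance (Beta distribution
of scaled squared distances under multivariate normality, Bonferroni over
the sample), applied iteratively.  The flag set is never applied
automatically — the exclusion decision stays with the user.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .core import ErpDataset, window_to_samples

__all__ = [
    "SubjectSimilarity",
    "MdsEmbedding",
    "FilterResult",
    "baseline_correct",
    "apply_filter",
    "subject_similarity",
    "mds_embed",
    "flag_outliers",
    "mahalanobis_distances",
]


@dataclass
class SubjectSimilarity:
    subject_ids: tuple
    matrix: np.ndarray  # symmetric, unit diagonal, in [-1, 1]


@dataclass
class MdsEmbedding:
    subject_ids: tuple
    coords: np.ndarray  # (n_subjects, dims), centered at the origin
    stress: float


@dataclass
class FilterResult:
    """Filtered dataset plus the settings applied ("Filter Specs")."""

    dataset: ErpDataset
    specs: dict
    original: ErpDataset | None = None

    def undo(self) -> ErpDataset:
        if self.original is None:
            raise ValueError("filter was applied without undoable=True")
        return self.original


def baseline_correct(ds: ErpDataset, window) -> ErpDataset:
    """Subtract, per channel, the mean over the baseline window (ms)."""
    first, last = window_to_samples(window, ds.dt, ds.t0, ds.n_timepoints)
    base = ds.data[:, :, first:last + 1].mean(axis=2, keepdims=True)
    return replace(ds, data=ds.data - base)


def apply_filter(ds: ErpDataset, low_cut: float | None = None,
                 high_cut: float | None = None, notch: float | None = None,
                 undoable: bool = False, order: int = 2,
                 notch_q: float = 30.0) -> FilterResult:
    """Zero-phase IIR filtering of every ERP in the dataset.

    ``low_cut``/``high_cut`` are Butterworth high-/low-pass corner
    frequencies in Hz (the names follow the convention of cutting away the
    low/high end); ``notch`` is a notch frequency.  Filters are applied
    forward-backward (zero phase) along time.
    """
    fs = 1000.0 / ds.dt
    nyq = fs / 2.0
    for name, f in (("low_cut", low_cut), ("high_cut", high_cut),
                    ("notch", notch)):
        if f is not None and not 0 < f < nyq:
            raise ValueError(f"{name} = {f} Hz must lie in (0, {nyq}) Hz")
    data = ds.data
    if low_cut is not None:
        sos = signal.butter(order, low_cut, btype="highpass", fs=fs,
                            output="sos")
        data = signal.sosfiltfilt(sos, data, axis=2)
    if high_cut is not None:
        sos = signal.butter(order, high_cut, btype="lowpass", fs=fs,
                            output="sos")
        data = signal.sosfiltfilt(sos, data, axis=2)
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=fs)
        data = signal.filtfilt(b, a, data, axis=2)
    specs = {"low_cut_hz": low_cut, "high_cut_hz": high_cut,
             "notch_hz": notch, "order": order, "zero_phase": True,
             "type": "butterworth"}
    return FilterResult(dataset=replace(ds, data=np.ascontiguousarray(data)),
                        specs=specs, original=ds if undoable else None)


def subject_similarity(ds: ErpDataset) -> SubjectSimilarity:
    """Pearson correlation of the subjects' flattened ERP data."""
    if ds.n_subjects < 3:
        raise ValueError("similarity screening requires at least 3 subjects")
    vectors = ds.data.reshape(ds.n_subjects, -1)
    sd = vectors.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(
            "zero-variance data for subject(s): "
            + ", ".join(ds.subject_ids[i] for i in flat))
    r = np.corrcoef(vectors)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SubjectSimilarity(subject_ids=ds.subject_ids, matrix=r)


def mds_embed(s: SubjectSimilarity, dims: int = 2) -> MdsEmbedding:
    """Classical metric MDS of the chord distances d = sqrt(2(1 − r)).

    Higher correlation between two subjects gives a smaller distance
    between their points; coordinates are centered so the origin is the
    mean of the data.  Stress is the relative root-mean-square
    misrepresentation of the input distances.
    """
    r = s.matrix
    d2 = 2.0 * (1.0 - r)  # squared chord distance
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)
    coords = coords - coords.mean(axis=0)
    emb = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    din = np.sqrt(np.clip(d2, 0.0, None))
    denom = (din ** 2).sum()
    stress = float(np.sqrt(((emb - din) ** 2).sum() / denom)) if denom else 0.0
    return MdsEmbedding(subject_ids=s.subject_ids, coords=coords,
                        stress=stress)


def mahalanobis_distances(points: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each point to the sample mean."""
    mu = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    inv = np.linalg.pinv(np.atleast_2d(cov))
    diff = points - mu
    return np.einsum("ij,jk,ik->i", diff, inv, diff)


def flag_outliers(e: MdsEmbedding, alpha: float = 0.05) -> set:
    """Iterative single-outlier test on the embedded points.

    At each step the point with the largest Mahalanobis distance is tested:
    under multivariate normality, n·d²/(n−1)² follows a
    Beta(p/2, (n−p−1)/2) distribution, and its tail probability is
    Bonferroni-corrected by n.  If significant at ``alpha`` the point is
    flagged and removed, and the test repeats.  The returned index set is
    advisory only.
    """
    points = np.asarray(e.coords, dtype=float)
    n, p = points.shape
    if n < 5:
        raise ValueError("outlier flagging requires at least 5 subjects")
    active = list(range(n))
    flagged = set()
    while len(active) >= 5:
        pts = points[active]
        m = len(active)
        d2 = mahalanobis_distances(pts)
        scaled = m * d2 / (m - 1) ** 2
        worst = int(np.argmax(d2))
        tail = stats.beta.sf(scaled[worst], p / 2.0, (m - p - 1) / 2.0)
        if min(1.0, tail * m) < alpha:
            flagged.add(active[worst])
            del active[worst]
        else:
            break
    return flagged
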