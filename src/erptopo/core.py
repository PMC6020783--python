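"""Data model and file I/O for averaged multichannel ERP data.

The atomic object of every analysis in this package is the *scalp map*: the
vector of potentials across all channels at one time point.  An averaged ERP
is a time × channel matrix of such maps; a study is a complete
subject × condition grid of these matrices (:class:`ErpDataset`) plus the
electrode montage.

All maps are treated as points in an n-channel state space.  Re-referencing
to the average reference centers those points at the origin, and the global
field power (GFP) — the population standard deviation of a map across
channels — is the distance of a map from the origin, corrected for the
number of channels.  GFP of a difference map is therefore the natural global
index of how much two scalp fields differ, and is the quantity all
randomization tests in this package are built on.

File formats are deliberately minimal plain text: whitespace-delimited
time × channel ASCII matrices (one file per subject and condition) and an
``xyz`` electrode-coordinate file.
"""

from __future__ import annotations

import glob as _glob
import os
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FormatError",
    "Montage",
    "ErpMatrix",
    "ErpDataset",
    "EffectCellMeans",
    "gfp",
    "average_reference",
    "normalize_by_gfp",
    "grand_mean",
    "read_erp_matrix",
    "read_montage",
    "import_dataset",
    "export_dataset",
    "load_dataset",
    "window_to_samples",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected plain-text format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Montage:
    """Electrode names and 3-D head-centered positions.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names, in data channel order.
    positions : ndarray of shape (n_channels, 3)
        Cartesian coordinates in arbitrary head-centered units.
    """

    labels: tuple
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("one position per label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class ErpMatrix:
    """One averaged ERP: a time × channel matrix in µV.

    ``dt`` is the inter-sample interval in ms, ``t0`` the time of the first
    sample relative to stimulus onset (ms; onset = 0).
    """

    samples: np.ndarray
    dt: float = 4.0
    t0: float = 0.0

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ValueError("samples must be a 2-D time × channel array")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.samples = s

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n_timepoints)


@dataclass
class ErpDataset:
    """Complete subject × condition grid of ERP matrices.

    The underlying storage is a single ``(n_subjects, n_conditions,
    n_timepoints, n_channels)`` array; every cell shares ``dt``, ``t0`` and
    the montage.  Missing cells are not supported (complete-case design).
    """

    data: np.ndarray
    subject_ids: tuple
    condition_tags: tuple
    dt: float = 4.0
    t0: float = 0.0
    montage: Montage | None = None
    is_average_referenced: bool = False

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError(
                "data must be (subjects, conditions, time, channels)")
        if d.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length mismatch")
        if d.shape[1] != len(self.condition_tags):
            raise ValueError("condition_tags length mismatch")
        if not np.all(np.isfinite(d)):
            raise ValueError("data must be finite")
        if self.montage is not None and self.montage.n_channels != d.shape[3]:
            raise ValueError(
                f"montage has {self.montage.n_channels} channels but data has "
                f"{d.shape[3]}")
        self.data = d
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.condition_tags = tuple(str(c) for c in self.condition_tags)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_timepoints)

    def get(self, subject, condition) -> ErpMatrix:
        """Return one cell as an :class:`ErpMatrix`."""
        si = self.subject_ids.index(str(subject))
        ci = self.condition_tags.index(str(condition))
        return ErpMatrix(self.data[si, ci].copy(), dt=self.dt, t0=self.t0)

    def average_referenced(self) -> "ErpDataset":
        """Return a copy with every map re-computed to average reference."""
        return replace(self, data=average_reference(self.data),
                       is_average_referenced=True)

    def slice_time(self, start: int, stop: int) -> "ErpDataset":
        """Sub-epoch by sample index (``stop`` inclusive)."""
        return replace(self, data=self.data[:, :, start:stop + 1].copy(),
                       t0=self.t0 + start * self.dt)


@dataclass
class EffectCellMeans:
    """Per-level grand-mean map series for one testable effect.

    ``level_means`` has shape (n_levels, n_timepoints, n_channels);
    ``overall_mean`` is the mean of the level means, so that for balanced
    designs the level deviations sum to zero.
    """

    level_means: np.ndarray
    overall_mean: np.ndarray
    level_labels: tuple = ()

    @property
    def level_count(self) -> int:
        return self.level_means.shape[0]


# ---------------------------------------------------------------------------
# map arithmetic
# ---------------------------------------------------------------------------


def gfp(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Global field power: population standard deviation across channels.

    GFP = sqrt( Σ_j (v_j − v̄)² / n ) over the ``axis`` holding channels.
    Reference-free; quantifies the overall strength of a scalp field.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < 2:
        raise ValueError("GFP requires at least 2 channels")
    return values.std(axis=axis)


def average_reference(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Subtract each map's channel mean (re-reference to the average).

    Idempotent; preserves all pairwise channel differences.
    """
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=axis, keepdims=True)


def normalize_by_gfp(values: np.ndarray, eps: float = 1e-12,
                     warn: bool = True):
    """Divide every map by its GFP so each time point has unit field strength.

    Maps with GFP ≤ ``eps`` are returned as all-zero and counted; a warning
    reports the count rather than raising, so randomization loops stay total.

    Returns
    -------
    normalized : ndarray
        Same shape as ``values``.
    n_degenerate : int
        Number of maps with sub-``eps`` GFP.
    """
    values = np.asarray(values, dtype=float)
    g = gfp(values)
    degenerate = g <= eps
    n_degenerate = int(degenerate.sum())
    safe = np.where(degenerate, 1.0, g)
    out = values / safe[..., None]
    out[degenerate] = 0.0
    if n_degenerate and warn:
        warnings.warn(
            f"{n_degenerate} map(s) with GFP <= {eps} set to zero during "
            "normalization", RuntimeWarning, stacklevel=2)
    return out, n_degenerate


def grand_mean(ds: ErpDataset, subjects=None,
               condition_weights=None) -> ErpMatrix:
    """Weighted grand mean across subjects and conditions.

    ``condition_weights`` must sum to 1 (a one-hot vector selects a single
    condition); default is equal weights over all conditions.
    """
    if subjects is None:
        idx = np.arange(ds.n_subjects)
    else:
        idx = np.asarray([ds.subject_ids.index(str(s)) for s in subjects])
    if idx.size == 0:
        raise ValueError("empty subject subset")
    if condition_weights is None:
        w = np.full(ds.n_conditions, 1.0 / ds.n_conditions)
    else:
        w = np.asarray(condition_weights, dtype=float)
        if w.shape != (ds.n_conditions,):
            raise ValueError("one weight per condition required")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("condition weights must sum to 1")
    m = np.tensordot(ds.data[idx].mean(axis=0), w, axes=([0], [0]))
    return ErpMatrix(m, dt=ds.dt, t0=ds.t0)


def window_to_samples(window, dt: float, t0: float, n_timepoints: int):
    """Map an inclusive ms window to (first, last) sample indices.

    Endpoints are mapped to the nearest sample and clipped to the epoch.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi < lo:
        raise ValueError("window end before start")
    first = int(round((lo - t0) / dt))
    last = int(round((hi - t0) / dt))
    if last < 0 or first > n_timepoints - 1:
        raise ValueError("window outside the recorded epoch")
    first = max(first, 0)
    last = min(last, n_timepoints - 1)
    return first, last


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_erp_matrix(path, transpose: bool = False, dt: float = 4.0,
                    t0: float = 0.0) -> ErpMatrix:
    """Read a whitespace-delimited ASCII time × channel matrix.

    With ``transpose=True`` the file is interpreted as channel × time and
    flipped during import.  Ragged rows or non-numeric tokens raise a
    :class:`FormatError` naming the offending line (and column).
    """
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}: line {lineno} has {len(tokens)} values, "
                    f"expected {width}")
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                for col, tok in enumerate(tokens, start=1):
                    try:
                        float(tok)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric value {tok!r} at line "
                            f"{lineno}, column {col}") from None
    if not rows:
        raise FormatError(f"{path}: empty file")
    arr = np.asarray(rows, dtype=float)
    if transpose:
        arr = arr.T
    return ErpMatrix(arr, dt=dt, t0=t0)


def read_montage(path) -> Montage:
    """Read an ``xyz`` electrode file.

    Two dialects are auto-detected from the first line's token count: an
    optional header line carrying the channel count, followed by one line
    per channel with three coordinates and an optional label.  Channels
    without a label are named ``Ch1``, ``Ch2``, ...
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty montage file")
    start = 0
    if len(lines[0]) < 3:
        # header line: channel count (extra tokens such as a scale ignored)
        try:
            declared = int(float(lines[0][0]))
        except ValueError:
            raise FormatError(f"{path}: unreadable header line") from None
        start = 1
        if len(lines) - 1 != declared:
            raise FormatError(
                f"{path}: header declares {declared} channels but file has "
                f"{len(lines) - 1}")
    labels, positions = [], []
    for lineno, tokens in enumerate(lines[start:], start=start + 1):
        if len(tokens) < 3:
            raise FormatError(f"{path}: line {lineno} has fewer than 3 "
                              "coordinates")
        try:
            xyz = [float(t) for t in tokens[:3]]
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric coordinate at line {lineno}") from None
        positions.append(xyz)
        labels.append(tokens[3] if len(tokens) > 3 else f"Ch{lineno - start}")
    return Montage(tuple(labels), np.asarray(positions))


def import_dataset(folder, search_expression: str, condition_tags,
                   transpose: bool = False, do_average_reference: bool = True,
                   dt: float = 4.0, t0: float = 0.0,
                   montage: Montage | None = None) -> ErpDataset:
    """Import a folder of per-subject-per-condition ASCII matrices.

    ``search_expression`` is a glob containing a single ``*`` capturing the
    subject identifier and the literal tag of one condition, e.g.
    ``"S*_C1.asc"`` for files named ``S01_C1.asc``; the tag is substituted
    to locate every condition's file for every discovered subject.
    Average referencing on import is strongly recommended and on by default.
    """
    condition_tags = [str(c) for c in condition_tags]
    anchor = next((c for c in condition_tags if c in search_expression), None)
    if anchor is None:
        raise ValueError(
            "search expression must contain one of the condition tags")
    if search_expression.count("*") != 1:
        raise ValueError(
            "search expression must contain exactly one '*' capturing the "
            "subject identifier")
    hits = sorted(_glob.glob(os.path.join(folder, search_expression)))
    if not hits:
        raise FileNotFoundError(
            f"no files match {search_expression!r} in {folder}")
    rx = re.compile(
        fnmatch_capture(search_expression))
    subjects = []
    for h in hits:
        m = rx.fullmatch(os.path.basename(h))
        if m:
            subjects.append(m.group(1))
    missing = []
    grid = []
    shape = None
    for s in subjects:
        row = []
        for c in condition_tags:
            fname = search_expression.replace(anchor, c, 1).replace("*", s)
            path = os.path.join(folder, fname)
            if not os.path.exists(path):
                missing.append((s, c))
                continue
            em = read_erp_matrix(path, transpose=transpose, dt=dt, t0=t0)
            if shape is None:
                shape = em.samples.shape
            elif em.samples.shape != shape:
                raise FormatError(
                    f"{path}: matrix is {em.samples.shape[0]} x "
                    f"{em.samples.shape[1]} but previous files were "
                    f"{shape[0]} x {shape[1]}")
            row.append(em.samples)
        grid.append(row)
    if missing:
        raise FileNotFoundError(
            "missing subject x condition files: "
            + ", ".join(f"({s}, {c})" for s, c in missing))
    data = np.asarray(grid)
    ds = ErpDataset(data, tuple(subjects), tuple(condition_tags), dt=dt,
                    t0=t0, montage=montage)
    if do_average_reference:
        ds = ds.average_referenced()
    return ds


def fnmatch_capture(pattern: str) -> str:
    """Translate a single-``*`` glob into a regex capturing the ``*`` part."""
    head, _, tail = pattern.partition("*")
    return re.escape(head) + "(.+)" + re.escape(tail)


def export_dataset(ds: ErpDataset, folder) -> None:
    """Write a dataset as an archival folder of ASCII matrices + manifest.

    Matrices are written with 17 significant digits so a round trip through
    :func:`load_dataset` is bit-exact.
    """
    os.makedirs(folder, exist_ok=True)
    for si, s in enumerate(ds.subject_ids):
        for ci, c in enumerate(ds.condition_tags):
            np.savetxt(os.path.join(folder, f"{s}_{c}.asc"),
                       ds.data[si, ci], fmt="%.17g")
    if ds.montage is not None:
        with open(os.path.join(folder, "montage.xyz"), "w") as fh:
            fh.write(f"{ds.montage.n_channels}\n")
            for lbl, pos in zip(ds.montage.labels, ds.montage.positions):
                fh.write(f"{pos[0]:.17g} {pos[1]:.17g} {pos[2]:.17g} {lbl}\n")
    with open(os.path.join(folder, "manifest.txt"), "w") as fh:
        fh.write(f"dt_ms = {ds.dt!r}\n")
        fh.write(f"t0_ms = {ds.t0!r}\n")
        fh.write(f"subjects = {' '.join(ds.subject_ids)}\n")
        fh.write(f"conditions = {' '.join(ds.condition_tags)}\n")
        fh.write(f"average_referenced = {int(ds.is_average_referenced)}\n")


def load_dataset(folder) -> ErpDataset:
    """Load a dataset archive written by :func:`export_dataset`."""
    manifest = {}
    with open(os.path.join(folder, "manifest.txt")) as fh:
        for line in fh:
            if "=" in line:
                key, val = line.split("=", 1)
                manifest[key.strip()] = val.strip()
    subjects = manifest["subjects"].split()
    conditions = manifest["conditions"].split()
    dt = float(manifest["dt_ms"])
    t0 = float(manifest["t0_ms"])
    montage_path = os.path.join(folder, "montage.xyz")
    montage = read_montage(montage_path) if os.path.exists(montage_path) else None
    data = np.asarray([
        [read_erp_matrix(os.path.join(folder, f"{s}_{c}.asc")).samples
         for c in conditions]
        for s in subjects])
    return ErpDataset(data, tuple(subjects), tuple(conditions), dt=dt, t0=t0,
                      montage=montage,
                      is_average_referenced=bool(int(
                          manifest.get("average_referenced", "0"))))
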