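"""Topographic consistency test (TCT).

Group ERP analysis assumes that, at a given latency, subjects activate at
least partially common sources.  The TCT makes that assumption testable:
the GFP of the grand-mean map across subjects is large when the individual
maps share a spatial configuration and shrinks toward zero when they do
not, because inconsistent potentials cancel in the average.

The null hypothesis — no communality of maps across subjects — is emulated
by shuffling, separately for each subject, the measured potentials of its
map across channels.  Each subject's GFP is preserved by construction; only
the spatial structure is destroyed.  The grand mean and its GFP are then
recomputed, and the p-value per time point is the (add-one) fraction of
shuffled grand-mean GFPs at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ErpDataset, average_reference, gfp
from .tanova import RandConfig, p_from_null

__all__ = ["TctResult", "tct"]


@dataclass
class TctResult:
    """Time series of observed grand-mean GFP and consistency p-values."""

    condition: str
    times: np.ndarray
    observed_gfp: np.ndarray
    p: np.ndarray
    n_runs: int
    threshold: float


def tct(ds: ErpDataset, condition: str, cfg: RandConfig = RandConfig()
        ) -> TctResult:
    """Test, per time point, whether subjects share a common topography.

    A fresh independent channel permutation is drawn per subject, per time
    point and per run (the test is defined time-point-wise).
    """
    if ds.n_subjects < 2:
        raise ValueError("TCT requires at least 2 subjects")
    if str(condition) not in ds.condition_tags:
        raise ValueError(f"condition {condition!r} not in dataset "
                         f"{ds.condition_tags}")
    ci = ds.condition_tags.index(str(condition))
    data = ds.data[:, ci]  # (S, T, C)
    if not ds.is_average_referenced:
        data = average_reference(data)
    S, T, C = data.shape
    observed = gfp(data.mean(axis=0))
    rng = np.random.default_rng(cfg.seed)
    R = cfg.n_runs
    null = np.empty((R, T))
    chunk = max(1, int(4_000_000 // max(1, S * T * C)))
    for start in range(0, R, chunk):
        stop = min(start + chunk, R)
        rc = stop - start
        keys = rng.random((rc, S, T, C))
        idx = np.argsort(keys, axis=-1)
        permuted = np.take_along_axis(
            np.broadcast_to(data, (rc, S, T, C)), idx, axis=-1)
        null[start:stop] = gfp(permuted.mean(axis=1))
    p = p_from_null(observed, null, cfg.legacy_p)
    return TctResult(condition=str(condition), times=ds.times,
                     observed_gfp=observed, p=p, n_runs=R,
                     threshold=cfg.p_threshold)
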