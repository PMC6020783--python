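"""Synthetic ERP datasets with known ground truth.

The generator emulates the data model every test in this package operates
on: per subject and condition, an average-referenced time × channel matrix
built as a sum of source template maps with smooth amplitude envelopes,
plus Gaussian noise.  Defaults mirror a typical multichannel ERP study
(16 subjects, 74 channels, 250 samples at 250 Hz, i.e. 0–996 ms).

Condition effects are stated explicitly and dissociate the two ways scalp
fields can differ:

* a *quantitative* effect scales all sources proportionally
  (``amplitude_scale``), changing GFP but not topography;
* a *qualitative* effect rotates a template within the plane spanned by
  two orthogonal templates (``rotation_deg``), changing topography at
  constant GFP;
* a *latency* effect shifts an activation in time (``latency_shift_ms``),
  the target of microstate timing statistics.

Subject variability adds per-subject amplitude gain and latency jitter;
noise is spatially uncorrelated per channel, optionally plus spatially
correlated noise (a random map with a random smooth time course).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ErpDataset, Montage, average_reference

__all__ = [
    "Activation",
    "ConditionEffect",
    "SyntheticSpec",
    "make_montage",
    "make_templates",
    "generate_dataset",
]


@dataclass(frozen=True)
class Activation:
    """One source activation: template index, window (ms) and peak µV."""

    template: int
    start_ms: float
    stop_ms: float
    amplitude: float = 10.0


@dataclass(frozen=True)
class ConditionEffect:
    amplitude_scale: float = 1.0
    rotation_deg: float = 0.0
    rotation_template: int = 0
    rotation_partner: int = 1
    latency_shift_ms: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_subjects: int = 16
    n_channels: int = 74
    n_timepoints: int = 250
    dt_ms: float = 4.0
    t0_ms: float = 0.0
    n_templates: int = 4
    condition_tags: tuple = ("A", "B")
    sequence: dict | None = None       # condition -> tuple of Activation
    effects: dict = field(default_factory=dict)  # condition -> ConditionEffect
    groups: tuple | None = None        # per-subject labels
    noise_sd: float = 2.0              # µV per channel, independent
    correlated_noise_sd: float = 0.0   # µV, one random map per cell
    subject_amp_sd: float = 0.1        # relative gain SD across subjects
    subject_latency_sd_ms: float = 0.0
    seed: int = 0


def make_montage(n_channels: int) -> Montage:
    """Deterministic quasi-uniform electrode positions on the upper
    hemisphere (Fibonacci lattice, unit radius)."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    z = (i + 0.5) / n_channels          # upper hemisphere only
    phi = 2 * np.pi * i / golden
    r = np.sqrt(1 - z ** 2)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    labels = tuple(f"E{j + 1}" for j in range(n_channels))
    return Montage(labels, pos)


def make_templates(k: int, n_channels: int, rng) -> np.ndarray:
    """k mutually orthogonal, zero-mean, unit-GFP source maps.

    Random Gaussian maps are orthogonalized (QR) against the constant
    vector, so at most ``n_channels − 1`` templates exist.
    """
    rng = np.random.default_rng(rng)
    if k > n_channels - 1:
        raise ValueError("at most n_channels - 1 orthogonal zero-mean maps")
    basis = np.column_stack([np.ones(n_channels),
                             rng.standard_normal((n_channels, k))])
    q, _ = np.linalg.qr(basis)
    maps = q[:, 1:1 + k].T               # orthonormal, orthogonal to 1
    return maps / maps.std(axis=1, keepdims=True)  # unit GFP


def default_sequence(spec: SyntheticSpec) -> dict:
    """Sequential activation of every template, shared by all conditions."""
    total = spec.n_timepoints * spec.dt_ms
    per = total / spec.n_templates
    acts = tuple(Activation(template=j, start_ms=spec.t0_ms + j * per,
                            stop_ms=spec.t0_ms + (j + 1) * per,
                            amplitude=10.0)
                 for j in range(spec.n_templates))
    return {tag: acts for tag in spec.condition_tags}


def _envelope(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Raised-cosine envelope over [start, stop] ms."""
    width = stop - start
    if width <= 0:
        return np.zeros_like(times)
    x = (times - start) / width
    env = 0.5 * (1 - np.cos(2 * np.pi * np.clip(x, 0, 1)))
    env[(x < 0) | (x > 1)] = 0.0
    return env


def generate_dataset(spec: SyntheticSpec):
    """Generate an :class:`ErpDataset` plus a ground-truth record.

    Returns
    -------
    ds : ErpDataset
        Average-referenced, with a deterministic montage attached.
    truth : dict
        ``templates`` (k × channels, unit GFP), ``sequence``, ``effects``
        and the per-condition effective template maps actually used.
    """
    rng = np.random.default_rng(spec.seed)
    montage = make_montage(spec.n_channels)
    templates = make_templates(spec.n_templates, spec.n_channels, rng)
    sequence = spec.sequence if spec.sequence is not None else \
        default_sequence(spec)
    times = spec.t0_ms + spec.dt_ms * np.arange(spec.n_timepoints)
    S, K = spec.n_subjects, len(spec.condition_tags)
    T, C = spec.n_timepoints, spec.n_channels
    gains = 1.0 + spec.subject_amp_sd * rng.standard_normal(S)
    jitter = spec.subject_latency_sd_ms * rng.standard_normal(S)
    data = np.zeros((S, K, T, C))
    used_maps = {}
    for ci, tag in enumerate(spec.condition_tags):
        eff = spec.effects.get(tag, ConditionEffect())
        cond_templates = templates.copy()
        if eff.rotation_deg:
            a, b = eff.rotation_template, eff.rotation_partner
            th = np.deg2rad(eff.rotation_deg)
            cond_templates[a] = (np.cos(th) * templates[a]
                                 + np.sin(th) * templates[b])
        used_maps[tag] = cond_templates
        for act in sequence[tag]:
            tmpl = cond_templates[act.template]
            for si in range(S):
                shift = eff.latency_shift_ms + jitter[si]
                env = _envelope(times, act.start_ms + shift,
                                act.stop_ms + shift)
                amp = act.amplitude * gains[si]
                data[si, ci] += amp * np.outer(env, tmpl)
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    if spec.correlated_noise_sd > 0:
        noise_map = rng.standard_normal((S, K, C))
        noise_map = average_reference(noise_map)
        noise_map /= noise_map.std(axis=-1, keepdims=True)
        course = rng.standard_normal((S, K, T))
        data += spec.correlated_noise_sd * course[..., None] \
            * noise_map[..., None, :]
    for ci, tag in enumerate(spec.condition_tags):
        scale = spec.effects.get(tag, ConditionEffect()).amplitude_scale
        if scale != 1.0:
            # a quantitative effect scales *all* active sources, noise
            # included: the condition's maps are exact scaled copies
            data[:, ci] *= scale
    data = average_reference(data)
    subject_ids = tuple(f"S{j + 1:02d}" for j in range(S))
    ds = ErpDataset(data, subject_ids, spec.condition_tags, dt=spec.dt_ms,
                    t0=spec.t0_ms, montage=montage,
                    is_average_referenced=True)
    truth = {"templates": templates, "sequence": sequence,
             "effects": dict(spec.effects), "condition_templates": used_maps,
             "subject_gains": gains, "subject_jitter_ms": jitter}
    return ds, truth
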