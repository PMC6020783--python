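"""Experimental designs and the permutations that define every null.

A design maps conditions to the levels of up to two fully crossed
within-subject factors and, optionally, subjects to groups of one
between-subject factor.  Every testable effect — each main effect, the
within×within interaction, the group effect and group×within interactions —
is enumerated from these assignments.

The randomization principle is uniform: to sample an effect statistic under
the null hypothesis, the link between predictor and data is destroyed by
shuffling condition labels independently within each subject (within-subject
effects) and/or shuffling group labels across subjects (between-subject
effects).  One shared shuffle per randomization run serves all effects, so
run-by-run null statistics are comparable across effects and reusable by the
overall statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .core import EffectCellMeans, ErpDataset, normalize_by_gfp

__all__ = [
    "Design",
    "PermutedAssignment",
    "define_design",
    "permute_design",
    "identity_assignment",
    "effect_cell_means",
]


@dataclass(frozen=True)
class PermutedAssignment:
    """One randomization run's shuffle.

    ``cond_perm[s, k]`` gives the original condition index placed in slot
    ``k`` for subject ``s`` (each row a bijection); ``subject_perm`` permutes
    subjects for the purpose of group-label assignment (the group multiset is
    preserved).  ``None`` means identity.
    """

    cond_perm: np.ndarray | None = None
    subject_perm: np.ndarray | None = None


@dataclass(frozen=True)
class Design:
    """Validated experimental design.

    ``within_factors`` maps factor name → {condition tag → level code};
    with two factors the level grid must be orthogonal (fully crossed, each
    cell exactly once).  ``scales`` marks a single within factor as
    categorical (default), rank or interval; non-categorical levels act as a
    linear contrast in the effect statistic.
    """

    condition_tags: tuple
    within_factors: tuple = ()          # ((name, {tag: level}), ...)
    groups: tuple | None = None         # per-subject labels, or None
    scales: tuple = ()                  # ((name, scale), ...)

    @property
    def factor_names(self):
        return tuple(name for name, _ in self.within_factors)

    @property
    def has_between(self) -> bool:
        return self.groups is not None

    def scale_of(self, name: str) -> str:
        return dict(self.scales).get(name, "categorical")

    def levels_of(self, name: str) -> np.ndarray:
        """Per-condition level codes for one within factor."""
        mapping = dict(self.within_factors)[name]
        return np.asarray([mapping[t] for t in self.condition_tags])

    @property
    def group_labels(self) -> tuple:
        return tuple(sorted(set(self.groups))) if self.groups else ()

    def group_index(self) -> np.ndarray:
        labels = self.group_labels
        return np.asarray([labels.index(g) for g in self.groups])

    @property
    def effects(self) -> tuple:
        """All testable effect identifiers for this design."""
        names = list(self.factor_names)
        eff = list(names)
        if len(names) == 2:
            eff.append(f"{names[0]}*{names[1]}")
        if self.has_between:
            eff.append("group")
            eff.extend(f"group*{n}" for n in names)
        return tuple(eff)

    def permutation_scope(self, effect: str) -> str:
        if effect == "group":
            return "between"
        if effect.startswith("group*"):
            return "both"
        return "within"


def define_design(factors, condition_tags, groups=None,
                  scales=None) -> Design:
    """Build and validate a :class:`Design`.

    Parameters
    ----------
    factors : mapping
        ``{factor name: {condition tag: level}}``, at most two factors.
    condition_tags : sequence of str
    groups : mapping or None
        ``{subject id: group label}`` — order must match the dataset — or a
        plain sequence of per-subject labels.
    scales : mapping or None
        ``{factor name: "categorical" | "rank" | "interval"}``.
    """
    condition_tags = tuple(str(t) for t in condition_tags)
    factors = dict(factors or {})
    if len(factors) > 2:
        raise ValueError("at most two within-subject factors are supported")
    for name, mapping in factors.items():
        missing = [t for t in condition_tags if t not in mapping]
        if missing:
            raise ValueError(
                f"factor {name!r} assigns no level to condition(s) "
                f"{missing}")
    if len(factors) == 2:
        (na, ma), (nb, mb) = factors.items()
        cells = [(ma[t], mb[t]) for t in condition_tags]
        expect = set(product(sorted(set(ma[t] for t in condition_tags)),
                             sorted(set(mb[t] for t in condition_tags))))
        if set(cells) != expect or len(cells) != len(expect):
            raise ValueError(
                f"factors {na!r} x {nb!r} are not orthogonal: each level "
                "combination must occur exactly once")
    scales = dict(scales or {})
    for name, sc in scales.items():
        if sc not in ("categorical", "rank", "interval"):
            raise ValueError(f"unknown scale {sc!r}")
        if sc != "categorical" and len(factors) == 2:
            raise ValueError("rank/interval scales require a single factor")
    if groups is not None and hasattr(groups, "values"):
        groups = tuple(groups.values())
    return Design(
        condition_tags=condition_tags,
        within_factors=tuple((n, dict(m)) for n, m in factors.items()),
        groups=tuple(groups) if groups is not None else None,
        scales=tuple(scales.items()),
    )


def identity_assignment() -> PermutedAssignment:
    return PermutedAssignment(None, None)


def permute_design(d: Design, rng: np.random.Generator, scope: str,
                   n_subjects: int | None = None) -> PermutedAssignment:
    """Draw one uniform random shuffle.

    ``scope='within'`` permutes each subject's condition labels
    independently and uniformly; ``'between'`` permutes group labels across
    subjects; ``'both'`` does both.
    """
    if scope not in ("within", "between", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope in ("between", "both") and not d.has_between:
        raise ValueError("between-scope permutation requires a between "
                         "factor")
    n_sub = n_subjects if n_subjects is not None else (
        len(d.groups) if d.groups else None)
    if n_sub is None:
        raise ValueError("n_subjects required for a design without groups")
    cond_perm = None
    subject_perm = None
    if scope in ("within", "both"):
        keys = rng.random((n_sub, len(d.condition_tags)))
        cond_perm = np.argsort(keys, axis=1)
    if scope in ("between", "both"):
        subject_perm = rng.permutation(n_sub)
    return PermutedAssignment(cond_perm, subject_perm)


# ---------------------------------------------------------------------------
# effect cell means
# ---------------------------------------------------------------------------


def apply_assignment(data: np.ndarray,
                     assignment: PermutedAssignment | None) -> np.ndarray:
    """Apply a condition shuffle to a (..., S, K, T, C) data array."""
    if assignment is None or assignment.cond_perm is None:
        return data
    idx = assignment.cond_perm[..., None, None]
    return np.take_along_axis(data, idx, axis=-3)


def _group_index(d: Design, assignment: PermutedAssignment | None):
    gi = d.group_index()
    if assignment is not None and assignment.subject_perm is not None:
        gi = gi[assignment.subject_perm]
    return gi


def effect_deviations(data: np.ndarray, d: Design, effect: str,
                      assignment: PermutedAssignment | None = None,
                      interaction: str = "residualized"):
    """Level means and their deviations from the overall mean for one effect.

    ``data`` is (S, K, T, C) (a leading runs axis is allowed for the
    condition-shuffle part of within effects).  Returns ``(level_means,
    deviations, overall)`` where deviations are what enters the dGFP sum.
    For rank/interval single-factor designs the "deviation" is the single
    linear-contrast map (centered level values as weights).
    """
    if effect not in d.effects:
        raise ValueError(f"effect {effect!r} not in design (has {d.effects})")
    data = apply_assignment(data, assignment)
    names = d.factor_names

    def within_level_means(levels):
        vals = np.unique(levels)
        means = np.stack([data[..., levels == v, :, :].mean(axis=(-4, -3))
                          for v in vals], axis=-3)
        return vals, means  # (..., L, T, C)

    if effect in names and d.scale_of(effect) != "categorical":
        # rank/interval single factor: linear contrast of the level means,
        # weights = centered (unit-norm) level values
        levels = d.levels_of(effect).astype(float)
        vals, means = within_level_means(levels)
        w = vals - vals.mean()
        w = w / np.sqrt((w ** 2).sum())
        contrast = np.einsum("l,...ltc->...tc", w, means)[..., None, :, :]
        overall = means.mean(axis=-3)
        return means, contrast, overall

    if effect in names:
        _, means = within_level_means(d.levels_of(effect))
        overall = means.mean(axis=-3, keepdims=True)
        return means, means - overall, overall[..., 0, :, :]

    if len(names) == 2 and effect == f"{names[0]}*{names[1]}":
        la = d.levels_of(names[0])
        lb = d.levels_of(names[1])
        avals, bvals = np.unique(la), np.unique(lb)
        cells = np.stack([
            np.stack([data[..., (la == a) & (lb == b), :, :].mean(axis=(-4, -3))
                      for b in bvals], axis=-3)
            for a in avals], axis=-4)  # (..., A, B, T, C)
        overall = cells.mean(axis=(-4, -3), keepdims=True)
        if interaction == "residualized":
            am = cells.mean(axis=-3, keepdims=True)
            bm = cells.mean(axis=-4, keepdims=True)
            dev = cells - am - bm + overall
        elif interaction == "raw":
            dev = cells - overall
        else:
            raise ValueError(f"unknown interaction mode {interaction!r}")
        shp = cells.shape[:-4] + (len(avals) * len(bvals),) + cells.shape[-2:]
        return (cells.reshape(shp), dev.reshape(shp),
                overall[..., 0, 0, :, :])

    # between-subject effect(s): group means over subjects
    gi = _group_index(d, assignment)
    n_groups = gi.max() + 1
    if effect == "group":
        means = np.stack([data[..., gi == g, :, :, :].mean(axis=(-4, -3))
                          for g in range(n_groups)], axis=-3)
        overall = means.mean(axis=-3, keepdims=True)
        return means, means - overall, overall[..., 0, :, :]

    # group × within interaction
    fname = effect.split("*", 1)[1]
    levels = d.levels_of(fname)
    vals = np.unique(levels)
    cells = np.stack([
        np.stack([data[..., gi == g, :, :, :][..., levels == v, :, :]
                  .mean(axis=(-4, -3)) for v in vals], axis=-3)
        for g in range(n_groups)], axis=-4)  # (..., G, L, T, C)
    overall = cells.mean(axis=(-4, -3), keepdims=True)
    gm = cells.mean(axis=-3, keepdims=True)
    lm = cells.mean(axis=-4, keepdims=True)
    dev = cells - gm - lm + overall
    shp = cells.shape[:-4] + (n_groups * len(vals),) + cells.shape[-2:]
    return cells.reshape(shp), dev.reshape(shp), overall[..., 0, 0, :, :]


def effect_cell_means(ds: ErpDataset, d: Design, effect: str,
                      assignment: PermutedAssignment | None = None,
                      normalize: bool = False,
                      interaction: str = "residualized") -> EffectCellMeans:
    """Grand-mean map series per level of one effect.

    Main effects give marginal means; interactions give cell-combination
    means (residualized deviations are used by the test statistic but the
    raw cell means are what is returned here); the between effect gives
    per-group means.  With ``normalize=True`` each subject × condition map
    is divided by its GFP at every time point before averaging.
    """
    data = ds.data
    if normalize:
        data, _ = normalize_by_gfp(data, warn=False)
    _, dev, overall = effect_deviations(data, d, effect, assignment,
                                        interaction)
    # level means are reported relative to the overall mean so that for
    # interactions the marginal main-effect patterns are already subtracted
    return EffectCellMeans(level_means=np.expand_dims(overall, -3) + dev,
                           overall_mean=overall)
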