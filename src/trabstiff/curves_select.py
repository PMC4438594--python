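"""Normalized-height parameter curves and caudal sub-region selection.

Slice-wise 2D parameters are graphed against the normalized height of the
trabecular cylinder (caudal 0 -> cranial 1).  Curves from the three lumbar
levels of each specimen are averaged per group, the group curves are
differenced, and the difference curves guide the choice of a contiguous
axial sub-region for finite-element analysis.  The fixed anatomical choice —
the caudal 40% of the cylinder — is available directly and is the pipeline
default; a reproducible scored selection (mean absolute normalized
difference over every contiguous window) is provided as the quantitative
surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterCurve",
    "RegionSelection",
    "resample_curve",
    "average_group",
    "difference_curve",
    "select_region",
    "fixed_caudal_selection",
]


@dataclass(frozen=True)
class ParameterCurve:
    """One structural parameter as a function of normalized height."""

    parameter: str
    grid: np.ndarray      # strictly increasing, endpoints 0 and 1
    values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if g.ndim != 1 or g.shape != v.shape or g.size < 2:
            raise ValueError("grid and values must be 1D, equal length >= 2")
        if not (np.all(np.diff(g) > 0) and g[0] == 0.0 and g[-1] == 1.0):
            raise ValueError("grid must be strictly increasing from 0 to 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.grid.size


@dataclass(frozen=True)
class RegionSelection:
    """A contiguous axial window chosen for finite-element analysis."""

    anchor: str                  # 'caudal' | 'cranial'
    fraction: float              # of the cylinder length, (0, 1]
    z_window: tuple[int, int]    # half-open slice range
    window_scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_slices(self) -> int:
        return self.z_window[1] - self.z_window[0]


def resample_curve(curve: ParameterCurve, n_points: int) -> ParameterCurve:
    """Linearly interpolate a curve onto a uniform n-point grid on [0, 1]."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(0.0, 1.0, n_points)
    values = np.interp(grid, curve.grid, curve.values)
    return ParameterCurve(curve.parameter, grid, values)


def average_group(curves: list[ParameterCurve], n_points: int = 100) -> ParameterCurve:
    """Pointwise mean of same-parameter curves after resampling to a common
    uniform grid (used to average the L4/L5/L6 curves of a group)."""
    if not curves:
        raise ValueError("no curves to average")
    names = {c.parameter for c in curves}
    if len(names) > 1:
        raise ValueError(f"mixed parameters: {sorted(names)}")
    res = [resample_curve(c, n_points) for c in curves]
    return ParameterCurve(curves[0].parameter, res[0].grid,
                          np.mean([c.values for c in res], axis=0))


def difference_curve(a: ParameterCurve, b: ParameterCurve,
                     n_points: int = 100) -> ParameterCurve:
    """a - b on a common uniform grid (e.g. sham minus OVX group curves)."""
    if a.parameter != b.parameter:
        raise ValueError(f"mixed parameters: {a.parameter} vs {b.parameter}")
    ra, rb = resample_curve(a, n_points), resample_curve(b, n_points)
    return ParameterCurve(a.parameter, ra.grid, ra.values - rb.values)


def fixed_caudal_selection(fraction: float, n_slices: int) -> RegionSelection:
    """The fixed anatomical choice: the caudal `fraction` of the cylinder."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    length = max(1, round(fraction * n_slices))
    return RegionSelection("caudal", fraction, (0, length))


def select_region(diffs: list[ParameterCurve], fraction: float,
                  n_slices: int) -> RegionSelection:
    """Score every contiguous window of the given fraction and pick the best.

    Each difference curve is resampled to the slice grid and rescaled to unit
    maximum absolute difference, so no single parameter's units dominate
    (separation runs opposite to the volume-fraction family, hence absolute
    values).  A window's score is the mean |difference| over its slices,
    averaged across curves; ties break toward the caudal end.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not diffs:
        raise ValueError("no difference curves")
    length = max(1, round(fraction * n_slices))
    profiles = []
    for c in diffs:
        v = np.abs(resample_curve(c, n_slices).values)
        peak = v.max()
        profiles.append(v / peak if peak > 0 else v)
    profile = np.mean(profiles, axis=0)
    n_windows = n_slices - length + 1
    scores = np.array([profile[s:s + length].mean() for s in range(n_windows)])
    best = int(np.argmax(scores))  # argmax returns the first (caudal-most) tie
    anchor = "caudal" if best <= (n_slices - (best + length)) else "cranial"
    return RegionSelection(anchor, fraction, (best, best + length), scores)
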