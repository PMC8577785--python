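"""Plateau/transition domain classification and model-characteristic curves.

The region of interest splits into a lower plateau (event probability ~0),
an upper plateau (~1), and the transition domain in between where the
probability is a sensitive function of the inputs.  For batches of
simulated realizations the split is exact — a set is on a plateau iff its
empirical frequency is exactly 0 or 1 — while for a logistic surrogate,
whose output is never exactly 0 or 1, it needs a probability band.  Both
classifiers are provided under distinct names.

A model-characteristic (MC) curve is the 1-D sweep of the surrogate's
predicted probability along one MMI axis with every other axis held fixed;
its steep section visualises the transition domain along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .lrm import BatchObservation, FittedLRM

__all__ = [
    "MCCurve",
    "classify_domain",
    "classify_empirical_domain",
    "mc_curve",
]

DEFAULT_BAND = (0.025, 0.975)

LOWER_PLATEAU = "lower_plateau"
TRANSITION = "transition"
UPPER_PLATEAU = "upper_plateau"


@dataclass(frozen=True)
class MCCurve:
    """Probability vs one MMI axis, other axes fixed (native units)."""

    axis: str
    grid: np.ndarray
    probabilities: np.ndarray
    fixed: np.ndarray  # the full fixed point; the swept coordinate is ignored


def classify_domain(
    model: FittedLRM,
    point: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
) -> str:
    """Band-based domain label for a surrogate prediction.

    lower_plateau iff P <= band_lo, upper_plateau iff P >= band_hi,
    transition otherwise.
    """
    lo, hi = band
    if not 0.0 < lo < hi < 1.0:
        raise ValueError(f"band must satisfy 0 < lo < hi < 1, got {band}")
    p = model.predict_probability(point)
    if p <= lo:
        return LOWER_PLATEAU
    if p >= hi:
        return UPPER_PLATEAU
    return TRANSITION


def classify_empirical_domain(observation: BatchObservation) -> str:
    """Strict domain label for simulated counts: plateau iff k is 0 or n."""
    if observation.k == 0:
        return LOWER_PLATEAU
    if observation.k == observation.n:
        return UPPER_PLATEAU
    return TRANSITION


def mc_curve(
    model: FittedLRM,
    axis: str,
    fixed: np.ndarray,
    grid_size: int = 201,
    value_range: Optional[tuple[float, float]] = None,
) -> MCCurve:
    """Sweep ``axis`` over ``value_range`` (default: its ROI bounds).

    The swept coordinate of ``fixed`` is overwritten point by point; the
    remaining coordinates are held at their fixed values.
    """
    i = model.space.index(axis)
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if value_range is None:
        value_range = (model.space.axes[i].lo, model.space.axes[i].hi)
    grid = np.linspace(value_range[0], value_range[1], grid_size)
    pts = np.tile(np.asarray(fixed, dtype=float), (grid_size, 1))
    pts[:, i] = grid
    probs = np.atleast_1d(model.predict_probability(pts))
    return MCCurve(axis=axis, grid=grid, probabilities=probs,
                   fixed=np.asarray(fixed, dtype=float))
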