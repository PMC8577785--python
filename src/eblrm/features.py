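"""Myocyte-model-input (MMI) spaces, min-max scaling and quadratic features.

A surrogate model for an arrhythmic-event probability is fitted not on raw
MMI values (which mix nanomolar concentrations with dimensionless scaling
factors) but on features scaled to [0, 1] over a biophysically plausible
region of interest (ROI), optionally augmented with quadratic terms.  This
module owns the bookkeeping: named axes with bounds and units, the affine
scaling and its inverse, and the construction of linear + quadratic design
vectors in a fixed, serializable order.

Scaling bounds are frozen with the model at fit time; prediction never
re-derives them from data, and points outside the ROI scale to values
outside [0, 1] without clipping (the surrogate is allowed to extrapolate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Axis",
    "MMISpace",
    "FeatureSpec",
    "scale_mmi",
    "unscale",
    "expand_features",
    "enumerate_quadratic_candidates",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent spaces, specs or model configurations."""


@dataclass(frozen=True)
class Axis:
    """One MMI axis: a name, [lo, hi] bounds in native units, and the unit."""

    name: str
    lo: float
    hi: float
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ConfigurationError(
                f"axis {self.name!r}: upper bound {self.hi} must exceed lower {self.lo}"
            )


@dataclass(frozen=True)
class MMISpace:
    """An ordered set of MMI axes — the region of interest is their box.

    The canonical 4-D space for the ectopic-beat study is built by
    :meth:`ectopic_beat_roi`: initial cytosolic Ca2+ (nM), initial SR Ca2+
    load (uM), and dimensionless scaling factors on the inward-rectifier K+
    conductance (G_K1) and the RyR opening rate.
    """

    axes: tuple[Axis, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate axis names in {names}")

    @classmethod
    def ectopic_beat_roi(cls) -> "MMISpace":
        return cls(
            (
                Axis("ca_i_ini", 100.0, 300.0, "nM"),
                Axis("ca_sr_ini", 300.0, 700.0, "uM"),
                Axis("g_k1_sf", 0.0, 1.0, "dimensionless"),
                Axis("k_ryr_sf", 0.5, 1.5, "dimensionless"),
            )
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def lower(self) -> np.ndarray:
        return np.array([a.lo for a in self.axes])

    @property
    def upper(self) -> np.ndarray:
        return np.array([a.hi for a in self.axes])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown axis {name!r}; axes are {self.names}") from None

    def point(self, **values: float) -> np.ndarray:
        """Build a point (native units, axis order) from keyword values."""
        missing = set(self.names) - set(values)
        extra = set(values) - set(self.names)
        if missing or extra:
            raise ConfigurationError(
                f"point must name every axis exactly once; missing={sorted(missing)}, "
                f"unknown={sorted(extra)}"
            )
        return np.array([float(values[n]) for n in self.names])

    def contains(self, point: np.ndarray) -> bool:
        point = np.asarray(point, dtype=float)
        return bool(np.all(point >= self.lower) and np.all(point <= self.upper))


def scale_mmi(point: np.ndarray, space: MMISpace) -> np.ndarray:
    """Min-max scale native-unit MMI values to the unit box of the ROI.

    x' = (x - lo) / (hi - lo), applied per axis along the last dimension.
    Points outside the ROI yield values outside [0, 1]; no clipping.
    """
    point = np.asarray(point, dtype=float)
    if point.shape[-1] != space.ndim:
        raise ConfigurationError(
            f"point has {point.shape[-1]} coordinates, space has {space.ndim} axes"
        )
    return (point - space.lower) / (space.upper - space.lower)


def unscale(scaled: np.ndarray, space: MMISpace) -> np.ndarray:
    """Exact inverse of :func:`scale_mmi` (native units from unit-box values)."""
    scaled = np.asarray(scaled, dtype=float)
    if scaled.shape[-1] != space.ndim:
        raise ConfigurationError(
            f"vector has {scaled.shape[-1]} coordinates, space has {space.ndim} axes"
        )
    return space.lower + scaled * (space.upper - space.lower)


def _format_term(term: tuple[str, ...]) -> str:
    if len(term) == 1:
        return term[0]
    a, b = term
    return f"{a}^2" if a == b else f"{a}*{b}"


def parse_term(name: str) -> tuple[str, ...]:
    """Parse a feature name ("x", "x^2", "x*y") back into an axis tuple."""
    if "*" in name:
        a, b = name.split("*")
        return (a, b)
    if name.endswith("^2"):
        return (name[:-2], name[:-2])
    return (name,)


@dataclass(frozen=True)
class FeatureSpec:
    """An ordered list of feature terms over named axes.

    Each term is a tuple of one axis name (linear) or two (quadratic; equal
    names denote a square).  The order of ``terms`` is the order of the
    design vector and of the fitted weights — interleaving linear and
    quadratic terms is allowed, so a published importance ranking can be
    used directly as the canonical order.
    """

    terms: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        canon = []
        for t in self.terms:
            if len(t) not in (1, 2):
                raise ConfigurationError(f"feature term {t} must have 1 or 2 axes")
            canon.append(tuple(sorted(t)))
        if len(set(canon)) != len(canon):
            raise ConfigurationError(f"duplicate feature terms in {self.terms}")

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "FeatureSpec":
        return cls(tuple(parse_term(n) for n in names))

    @classmethod
    def linear_only(cls, space: MMISpace) -> "FeatureSpec":
        return cls(tuple((n,) for n in space.names))

    @classmethod
    def with_quadratics(
        cls, space: MMISpace, quadratic: Sequence[tuple[str, str]]
    ) -> "FeatureSpec":
        """All linear terms (axis order) followed by the given quadratic terms."""
        return cls(tuple((n,) for n in space.names) + tuple(tuple(q) for q in quadratic))

    @classmethod
    def full_quadratic(cls, space: MMISpace) -> "FeatureSpec":
        return cls.with_quadratics(space, enumerate_quadratic_candidates(space))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(_format_term(t) for t in self.terms)

    @property
    def linear_terms(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms if len(t) == 1)

    @property
    def quadratic_terms(self) -> tuple[tuple[str, str], ...]:
        return tuple(t for t in self.terms if len(t) == 2)  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self.terms)

    def validate_against(self, space: MMISpace) -> None:
        known = set(space.names)
        for t in self.terms:
            for name in t:
                if name not in known:
                    raise ConfigurationError(
                        f"feature term {_format_term(t)!r} references unknown axis {name!r}"
                    )

    def uses_axis_quadratically(self, axis: str) -> bool:
        return any(axis in t for t in self.quadratic_terms)


def expand_features(
    scaled: np.ndarray, spec: FeatureSpec, space: MMISpace
) -> np.ndarray:
    """Build the design vector(s) from scaled coordinates.

    Linear entries are copied; a quadratic entry (i, j) is the product
    x'_i * x'_j.  Works on a single vector or a (m, d) array of rows.
    """
    spec.validate_against(space)
    scaled = np.asarray(scaled, dtype=float)
    idx = {n: i for i, n in enumerate(space.names)}
    cols = []
    for t in spec.terms:
        if len(t) == 1:
            cols.append(scaled[..., idx[t[0]]])
        else:
            cols.append(scaled[..., idx[t[0]]] * scaled[..., idx[t[1]]])
    return np.stack(cols, axis=-1)


def enumerate_quadratic_candidates(space: MMISpace) -> list[tuple[str, str]]:
    """All d(d+1)/2 quadratic terms (squares + cross products), fixed order.

    Order: for axes i <= j in space order, the term (name_i, name_j).
    """
    names = space.names
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i, len(names))
    ]
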