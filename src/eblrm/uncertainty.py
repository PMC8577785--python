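"""Propagation of MMI measurement uncertainty through the surrogate.

Experimentally measured MMIs carry uncertainty; modelling each uncertain
input as an independent normal N(mean, sigma^2) makes the surrogate's
output P(event) itself a random variable.  This module characterises that
induced distribution:

* Monte Carlo propagation (default 10^6 draws, no truncation at the region
  of interest — the surrogate extrapolates);
* the analytic logit-normal density, valid when exactly one input is
  uncertain and enters the model only linearly, so the linear predictor is
  itself normal;
* summary measures suited to distributions on [0, 1]: mean, SD, Shannon
  entropy of the binned distribution (variance understates the spread of a
  bimodal shape; entropy does not), and a coarse modality label
  (unimodal / uniform_like / bimodal).

The characteristic phenomenology: for a point in the middle of the
transition domain, growing input uncertainty first spreads a unimodal
P(event) distribution into a near-uniform one (entropy rises) and then
piles mass onto the plateaus at 0 and 1 (bimodal; entropy falls again),
while the mean converges to 0.5 whatever the starting point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .features import ConfigurationError
from .lrm import FittedLRM

__all__ = [
    "UncertaintySpec",
    "ProbabilityDistribution",
    "propagate_mc",
    "logit_normal_pdf",
    "analytic_distribution",
    "entropy",
    "classify_modality",
    "mean_p_vs_sigma",
]

UNIMODAL = "unimodal"
UNIFORM_LIKE = "uniform_like"
BIMODAL = "bimodal"


@dataclass(frozen=True)
class UncertaintySpec:
    """Independent normal uncertainty per axis; sigma = 0 pins an axis.

    ``means`` and ``sigmas`` are keyed by axis name in native units and
    must cover every axis of the space they are used with.
    """

    means: dict[str, float]
    sigmas: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sigmas):
            raise ConfigurationError("means and sigmas must name the same axes")
        bad = {k: v for k, v in self.sigmas.items() if v < 0}
        if bad:
            raise ConfigurationError(f"negative sigmas: {bad}")

    def validate_against(self, model: FittedLRM) -> None:
        if set(self.means) != set(model.space.names):
            raise ConfigurationError(
                f"uncertainty spec axes {sorted(self.means)} do not match "
                f"model axes {sorted(model.space.names)}"
            )

    @property
    def uncertain_axes(self) -> tuple[str, ...]:
        return tuple(a for a, s in self.sigmas.items() if s > 0)

    def with_sigma(self, axis: str, sigma: float) -> "UncertaintySpec":
        return UncertaintySpec(dict(self.means), {**self.sigmas, axis: sigma})


@dataclass(frozen=True)
class ProbabilityDistribution:
    """The induced distribution of P(event) on [0, 1].

    Histogram masses are on ``bins`` equal-width bins; for Monte Carlo
    results the raw samples are retained, for analytic results
    ``samples`` is None and ``analytic`` is True.
    """

    bin_edges: np.ndarray
    masses: np.ndarray
    mean: float
    sd: float
    n_samples: int
    samples: Optional[np.ndarray] = None
    analytic: bool = False

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.masses)) - 1.0) > 1e-9:
            raise ValueError("histogram masses must sum to 1")


def _histogram(samples: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(samples, bins=bins, range=(0.0, 1.0))
    return edges, counts / counts.sum()


def propagate_mc(
    model: FittedLRM,
    uspec: UncertaintySpec,
    n_samples: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    bins: int = 100,
) -> ProbabilityDistribution:
    """Monte Carlo distribution of P(event) under normal MMI uncertainty.

    Each uncertain axis is drawn independently from N(mean, sigma^2) with
    no truncation or clipping at the region of interest; the surrogate is
    evaluated per draw.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    uspec.validate_against(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = np.empty((n_samples, model.space.ndim))
    for i, name in enumerate(model.space.names):
        mu, sd = uspec.means[name], uspec.sigmas[name]
        pts[:, i] = rng.normal(mu, sd, n_samples) if sd > 0 else mu
    p = np.atleast_1d(model.predict_probability(pts))
    edges, masses = _histogram(p, bins)
    return ProbabilityDistribution(
        bin_edges=edges, masses=masses,
        mean=float(p.mean()), sd=float(p.std(ddof=0)),
        n_samples=n_samples, samples=p,
    )


def logit_normal_pdf(p: np.ndarray | float, mu_y: float, sigma_y: float):
    """Density of logistic(Y) at p, where Y ~ N(mu_y, sigma_y^2).

    f(p) = 1 / (sigma_y sqrt(2 pi)) * 1 / (p (1-p)) *
           exp(-(logit(p) - mu_y)^2 / (2 sigma_y^2)),  0 < p < 1.
    """
    if sigma_y <= 0:
        raise ValueError("sigma_y must be positive")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    z = (logit(p_arr) - mu_y) / sigma_y
    out = np.exp(-0.5 * z * z) / (sigma_y * np.sqrt(2 * np.pi) * p_arr * (1 - p_arr))
    return float(out) if np.ndim(p) == 0 else out


def analytic_distribution(
    model: FittedLRM,
    uspec: UncertaintySpec,
    bins: int = 100,
) -> Optional[ProbabilityDistribution]:
    """Exact logit-normal distribution of P(event), where applicable.

    Applicable iff exactly one axis is uncertain and that axis enters the
    model through its linear term only: then the linear predictor is
    normal with mean b0 + B^T x(means) and SD |w_axis| * sigma / (hi - lo),
    and P(event) is logit-normal.  Returns None otherwise (quadratic
    involvement or multiple uncertain axes); callers fall back to
    :func:`propagate_mc`.

    Mean and SD are computed by Gauss-Hermite quadrature over the normal
    linear predictor; histogram masses are exact normal-CDF differences.
    """
    uspec.validate_against(model)
    unc = uspec.uncertain_axes
    if len(unc) != 1:
        return None
    axis = unc[0]
    if model.spec.uses_axis_quadratically(axis):
        return None
    try:
        w_idx = model.spec.terms.index((axis,))
    except ValueError:
        return None  # uncertain axis absent from the model: degenerate case
    ax = model.space.axes[model.space.index(axis)]
    mean_point = model.space.point(**uspec.means)
    mu_y = float(model.linear_predictor(mean_point))
    sigma_y = abs(model.weights[w_idx]) * uspec.sigmas[axis] / (ax.hi - ax.lo)

    edges = np.linspace(0.0, 1.0, bins + 1)
    with np.errstate(divide="ignore"):
        z = (logit(edges) - mu_y) / sigma_y  # +-inf at the boundary edges
    cdf = norm.cdf(z)
    masses = np.diff(cdf)
    masses = masses / masses.sum()

    nodes, wts = np.polynomial.hermite_e.hermegauss(201)
    y = mu_y + sigma_y * nodes
    probs = expit(y)
    wts = wts / wts.sum()
    mean = float(probs @ wts)
    sd = float(np.sqrt(max((probs - mean) ** 2 @ wts, 0.0)))
    return ProbabilityDistribution(
        bin_edges=edges, masses=masses, mean=mean, sd=sd,
        n_samples=0, samples=None, analytic=True,
    )


def entropy(dist: ProbabilityDistribution) -> float:
    """Shannon entropy (nats) of the binned distribution: -sum m_i ln m_i."""
    m = dist.masses[dist.masses > 0]
    return float(-np.sum(m * np.log(m)))


def classify_modality(
    dist: ProbabilityDistribution,
    smooth_window: int = 3,
    uniform_ratio: float = 3.0,
    edge_mass_min: float = 0.02,
) -> str:
    """Coarse shape label: unimodal, uniform_like, or bimodal.

    The histogram is smoothed with a short reflect-padded moving average
    (raw bin masses at 10^6 samples are noisy at the bin scale).  A
    distribution whose largest smoothed bin mass is within a factor
    ``uniform_ratio`` of the median bin mass is uniform_like (a genuinely
    flat histogram has every bin near 1/n_bins; any pronounced peak blows
    the ratio up).  Otherwise, mass piling into strict local maxima at
    *both* outermost bins — probability concentrating on the two plateaus,
    each holding at least ``edge_mass_min`` of the total — is bimodal, and
    anything else (one peak, wherever it sits) unimodal.
    """
    m = dist.masses.astype(float)
    if smooth_window > 1:
        pad = smooth_window // 2
        padded = np.concatenate([m[pad - 1 :: -1], m, m[: -pad - 1 : -1]])
        kernel = np.ones(smooth_window) / smooth_window
        m = np.convolve(padded, kernel, mode="valid")
    med = float(np.median(m))
    if med > 0 and m.max() / med < uniform_ratio:
        return UNIFORM_LIKE
    raw = dist.masses
    if m[0] > m[1] and m[-1] > m[-2] and min(raw[0], raw[-1]) >= edge_mass_min:
        return BIMODAL
    return UNIMODAL


def mean_p_vs_sigma(
    model: FittedLRM,
    uspec: UncertaintySpec,
    axis: str,
    sigma_grid: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean propagated P(event) as the uncertainty of one axis grows.

    ``uspec`` provides the means (and any other fixed sigmas); its sigma on
    ``axis`` is replaced by each grid value in turn.  sigma = 0 reduces to
    the point prediction.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(np.diff(sigma_grid) < 0) or np.any(sigma_grid < 0):
        raise ValueError("sigma_grid must be non-negative and non-decreasing")
    root = np.random.SeedSequence(seed)
    means = np.empty(len(sigma_grid))
    for i, (s, ss) in enumerate(zip(sigma_grid, root.spawn(len(sigma_grid)))):
        spec_i = uspec.with_sigma(axis, float(s))
        if not spec_i.uncertain_axes:
            means[i] = float(model.predict_probability(
                model.space.point(**spec_i.means)))
        else:
            means[i] = propagate_mc(
                model, spec_i, n_samples=n_samples,
                seed=np.random.default_rng(ss),
            ).mean
    return sigma_grid, means
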