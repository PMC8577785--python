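"""Binomial logistic regression on batched event counts.

The surrogate ("LRM") maps scaled MMI features to an event probability
through P = 1 / (1 + exp(-(b0 + B^T x))).  Training data are per-MMI-set
binomial counts: k events out of n stochastic realizations.  The fit is
maximum likelihood on those counts via iteratively reweighted least
squares (IRLS), which gives the identical ML solution to expanding every
realization into a Bernoulli row at a fraction of the cost.

Standard errors come from the observed information matrix at the optimum;
feature importance is ranked by absolute weight on the [0, 1]-scaled
features, so weights are directly comparable across axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, gammaln, logit

from .features import (
    ConfigurationError,
    FeatureSpec,
    MMISpace,
    expand_features,
    scale_mmi,
)

__all__ = [
    "BatchObservation",
    "FittedLRM",
    "ValidationReport",
    "FitError",
    "SeparationError",
    "fit_lrm",
    "derive_intercept_from_anchor",
    "submodel",
    "validate",
]


class FitError(RuntimeError):
    """Model fit failed; carries iteration diagnostics."""

    def __init__(self, message: str, *, iterations: int | None = None):
        super().__init__(message)
        self.iterations = iterations


class SeparationError(FitError):
    """Complete separation: the ML weights are unbounded."""


@dataclass(frozen=True)
class BatchObservation:
    """One MMI set with k events observed in n realizations."""

    point: np.ndarray
    k: int
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k must satisfy 0 <= k <= n, got k={self.k}, n={self.n}")

    @property
    def p_hat(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class ValidationReport:
    """Surrogate-vs-observed agreement summary.

    ``r2_transition`` is the squared Pearson correlation between predicted
    and observed probabilities restricted to transition-domain sets
    (0 < p_hat < 1); it is NaN when fewer than 3 such sets exist.
    ``mean_abs_error`` / ``sd_abs_error`` summarize |p_hat - predicted|
    over all sets.
    """

    r2_all: float
    r2_transition: float
    mean_abs_error: float
    sd_abs_error: float
    n_transition: int


@dataclass(frozen=True)
class FittedLRM:
    """A fitted (or reconstructed) logistic surrogate.

    Holds the frozen scaling space, the feature specification, intercept,
    per-feature weights and (when available) their standard errors.
    ``provenance`` is "fit" for models estimated from data and
    "reconstructed" for models rebuilt from published weights.
    """

    space: MMISpace
    spec: FeatureSpec
    intercept: float
    weights: np.ndarray
    se: Optional[np.ndarray] = None
    intercept_se: Optional[float] = None
    log_likelihood: Optional[float] = None
    n_obs: Optional[int] = None
    provenance: str = "fit"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        self.spec.validate_against(self.space)
        if len(self.weights) != len(self.spec):
            raise ConfigurationError(
                f"{len(self.weights)} weights for {len(self.spec)} features"
            )
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if len(se) != len(self.weights) or np.any(se < 0):
                raise ConfigurationError("se must be non-negative, one per weight")
            object.__setattr__(self, "se", se)

    # ---- prediction -------------------------------------------------
    def features(self, point: np.ndarray) -> np.ndarray:
        return expand_features(scale_mmi(point, self.space), self.spec, self.space)

    def linear_predictor(self, point: np.ndarray) -> np.ndarray | float:
        """b0 + B^T x on scaled features; vectorized over rows of points."""
        eta = self.intercept + self.features(point) @ self.weights
        return float(eta) if np.ndim(eta) == 0 else eta

    def predict_probability(self, point: np.ndarray) -> np.ndarray | float:
        """Event probability via the logistic link; stable for |eta| up to ~700."""
        p = expit(self.linear_predictor(point))
        return float(p) if np.ndim(p) == 0 else p

    def rank_features(self) -> list[tuple[str, float, Optional[float]]]:
        """Features by descending |weight|; ties keep the canonical spec order."""
        order = sorted(
            range(len(self.weights)), key=lambda i: (-abs(self.weights[i]), i)
        )
        ses = self.se if self.se is not None else [None] * len(self.weights)
        return [(self.spec.names[i], float(self.weights[i]), ses[i]) for i in order]


def _design_matrix(
    observations: Sequence[BatchObservation], space: MMISpace, spec: FeatureSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = np.array([o.point for o in observations])
    F = expand_features(scale_mmi(pts, space), spec, space)
    X = np.column_stack([np.ones(len(observations)), F])
    k = np.array([o.k for o in observations], dtype=float)
    n = np.array([o.n for o in observations], dtype=float)
    return X, k, n


def _binomial_loglik(k: np.ndarray, n: np.ndarray, eta: np.ndarray) -> float:
    # log C(n,k) + k*eta - n*log(1 + exp(eta)), with a stable log1pexp
    log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + k * eta - n * log1pexp))


def fit_lrm(
    observations: Sequence[BatchObservation],
    space: MMISpace,
    spec: FeatureSpec,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
    separation_weight: float = 1e3,
) -> FittedLRM:
    """Maximum-likelihood binomial fit by IRLS on (k, n) counts.

    Convergence: relative log-likelihood change < ``tol`` (default 1e-10)
    within ``max_iter`` iterations.  Non-convergence raises :class:`FitError`
    with iteration diagnostics; if the diverged weights are huge
    (> ``separation_weight``) or every fitted probability is saturated, a
    :class:`SeparationError` is raised instead.
    """
    spec.validate_against(space)
    n_params = len(spec) + 1
    if len(observations) < n_params:
        raise FitError(
            f"need at least {n_params} observations to fit {n_params} parameters, "
            f"got {len(observations)}"
        )
    # constant p_hat strictly inside (0,1) still identifies the intercept-only
    # solution; constant 0 or 1 makes the likelihood unbounded (separation)
    phats = {o.k / o.n for o in observations}
    if phats in ({0.0}, {1.0}):
        raise SeparationError(
            "every observed event fraction is exactly "
            f"{phats.pop():g}; the ML weights are unbounded"
        )

    X, k, n = _design_matrix(observations, space, spec)
    beta = np.zeros(n_params)
    ll_old = _binomial_loglik(k, n, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(n * mu * (1.0 - mu), 1e-12)
        z = eta + (k - n * mu) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular weighted design at iteration {it}: {exc}",
                           iterations=it) from exc
        ll = _binomial_loglik(k, n, X @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + tol):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    mu = expit(X @ beta)
    if not converged:
        saturated = np.all((mu < 1e-8) | (mu > 1 - 1e-8))
        if np.max(np.abs(beta)) > separation_weight or saturated:
            raise SeparationError(
                "complete separation detected: unbounded weights "
                f"(max |weight| = {np.max(np.abs(beta)):.3g} after {it} iterations)",
                iterations=it,
            )
        raise FitError(f"IRLS did not converge in {max_iter} iterations",
                       iterations=it)

    w = np.maximum(n * mu * (1.0 - mu), 1e-12)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(n_params, np.nan)

    return FittedLRM(
        space=space,
        spec=spec,
        intercept=float(beta[0]),
        weights=beta[1:],
        se=se_all[1:],
        intercept_se=float(se_all[0]),
        log_likelihood=ll_old,
        n_obs=len(observations),
        provenance="fit",
    )


def derive_intercept_from_anchor(
    weights: np.ndarray,
    space: MMISpace,
    spec: FeatureSpec,
    anchor: np.ndarray,
    anchor_p: float,
) -> float:
    """Intercept that makes the model hit ``anchor_p`` exactly at ``anchor``.

    b0 = logit(anchor_p) - B^T x(anchor).  Used to reconstruct a model whose
    published description gives the weights and one (point, probability)
    pair but no intercept.
    """
    if not 0.0 < anchor_p < 1.0:
        raise ValueError(f"anchor probability must be in (0, 1), got {anchor_p}")
    weights = np.asarray(weights, dtype=float)
    feats = expand_features(scale_mmi(anchor, space), spec, space)
    return float(logit(anchor_p) - feats @ weights)


def submodel(
    model: FittedLRM,
    observations: Sequence[BatchObservation],
    top_n: int,
    **fit_kwargs,
) -> FittedLRM:
    """Refit on the same observations keeping only the top_n ranked features."""
    if not 1 <= top_n <= len(model.spec):
        raise ValueError(
            f"top_n must be in [1, {len(model.spec)}], got {top_n}"
        )
    keep = [name for name, _, _ in model.rank_features()[:top_n]]
    # preserve the parent spec's canonical term order
    sub = FeatureSpec(tuple(t for t, n in zip(model.spec.terms, model.spec.names)
                            if n in set(keep)))
    return fit_lrm(observations, model.space, sub, **fit_kwargs)


def validate(
    model: FittedLRM, observations: Sequence[BatchObservation]
) -> ValidationReport:
    """Mean absolute error over all sets; R^2 inside the transition domain.

    Error_i = |p_hat_i - P_LRM(point_i)|; the transition domain is the set
    of observations with empirical probability strictly between 0 and 1.
    """
    if not observations:
        raise ValueError("observations must be non-empty")
    pts = np.array([o.point for o in observations])
    p_hat = np.array([o.p_hat for o in observations])
    pred = np.atleast_1d(model.predict_probability(pts))
    abs_err = np.abs(p_hat - pred)

    def _r2(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    trans = (p_hat > 0) & (p_hat < 1)
    return ValidationReport(
        r2_all=_r2(p_hat, pred),
        r2_transition=_r2(p_hat[trans], pred[trans]),
        mean_abs_error=float(abs_err.mean()),
        sd_abs_error=float(abs_err.std(ddof=0)),
        n_transition=int(trans.sum()),
    )
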