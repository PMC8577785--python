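"""Two-iteration sampling design and quadratic-feature selection.

The event-probability surface of a stochastic myocyte model is steep: most
of the MMI region of interest sits on probability plateaus at ~0 or ~1, and
the informative "transition domain" in between is narrow.  Uniform sampling
alone therefore wastes most of its budget.  The pipeline implemented here
samples in two iterations:

1. uniform sampling of the region of interest, a batch of realizations per
   sampled MMI set, and a preliminary linear-features-only logistic fit;
2. rejection sampling of the transition domain — uniform proposals kept
   only where the preliminary model predicts a probability inside a
   configurable band — followed by another round of simulated batches.

The pooled observations from both iterations then drive an exhaustive
search over all 2^(d(d+1)/2) quadratic-feature subsets (every candidate
keeps all linear terms); the subset minimising a consistent-AIC criterion
defines the final model's feature vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureSpec, MMISpace, enumerate_quadratic_candidates
from .lrm import BatchObservation, FitError, FittedLRM, fit_lrm
from .toy_myocyte import ToyModelConfig, simulate_batch

__all__ = [
    "PipelineConfig",
    "IterationResult",
    "PipelineResult",
    "TransitionSamplingError",
    "sample_roi",
    "sample_transition",
    "caic",
    "select_feature_set",
    "run_two_iteration_pipeline",
]

MAX_EXHAUSTIVE_AXES = 5  # 2^15 = 32768 candidate fits


class TransitionSamplingError(RuntimeError):
    """Transition-domain rejection sampling starved; widen the band."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the two-iteration design.

    Defaults follow the published study: 100 MMI sets per iteration, 100
    realizations per set, CAIC selection.  ``transition_band`` bounds the
    preliminary-model probability accepted in iteration 2;
    ``sample_size_convention`` picks the N used in the criterion penalty
    (total Bernoulli trials vs number of MMI sets).
    """

    space: MMISpace
    sets_per_iteration: int = 100
    realizations_per_set: int = 100
    transition_band: tuple[float, float] = (0.025, 0.975)
    criterion: Literal["caic", "aic"] = "caic"
    sample_size_convention: Literal["total_trials", "n_sets"] = "total_trials"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.transition_band
        if not 0.0 < lo < hi < 1.0:
            raise ValueError(f"transition band must satisfy 0 < lo < hi < 1, got {self.transition_band}")
        if self.sets_per_iteration < 1 or self.realizations_per_set < 1:
            raise ValueError("sets_per_iteration and realizations_per_set must be >= 1")
        if self.criterion not in ("caic", "aic"):
            raise ValueError(f"criterion must be 'caic' or 'aic', got {self.criterion!r}")
        if self.sample_size_convention not in ("total_trials", "n_sets"):
            raise ValueError(f"unknown sample_size_convention {self.sample_size_convention!r}")


@dataclass(frozen=True)
class IterationResult:
    observations: tuple[BatchObservation, ...]
    model: FittedLRM
    iteration: int


@dataclass(frozen=True)
class PipelineResult:
    model: FittedLRM
    iterations: tuple[IterationResult, IterationResult]
    selection_table: pd.DataFrame
    config: PipelineConfig


def sample_roi(space: MMISpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points drawn coordinate-wise uniform over the region of interest."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    u = rng.random((n, space.ndim))
    return space.lower + u * (space.upper - space.lower)


def sample_transition(
    space: MMISpace,
    prelim_model: FittedLRM,
    n: int,
    band: tuple[float, float],
    rng: np.random.Generator,
    *,
    min_acceptance: float = 1e-5,
) -> np.ndarray:
    """Rejection-sample n points whose preliminary prediction lies in ``band``.

    Uniform proposals over the space are kept iff the preliminary model's
    predicted probability satisfies band_lo <= p <= band_hi.  Raises
    :class:`TransitionSamplingError` once the proposal budget implies an
    acceptance rate below ``min_acceptance``.
    """
    lo, hi = band
    accepted: list[np.ndarray] = []
    proposed = 0
    budget = max(10_000, math.ceil(n / min_acceptance))
    chunk = max(1024, 4 * n)
    while sum(len(a) for a in accepted) < n:
        if proposed >= budget:
            rate = sum(len(a) for a in accepted) / proposed
            raise TransitionSamplingError(
                f"acceptance rate {rate:.2e} after {proposed} proposals; "
                f"widen the transition band {band} or check the preliminary model"
            )
        pts = sample_roi(space, chunk, rng)
        p = np.atleast_1d(prelim_model.predict_probability(pts))
        keep = (p >= lo) & (p <= hi)
        accepted.append(pts[keep])
        proposed += chunk
    return np.concatenate(accepted)[:n]


def caic(
    log_likelihood: float,
    n_params: int,
    sample_size: int,
    criterion: str = "caic",
) -> float:
    """Model-selection criterion.

    "caic" is the consistent AIC, -2 lnL + k (ln N + 1); "aic" is the
    classical -2 lnL + 2 k.
    """
    if sample_size < 1:
        raise ValueError(f"sample_size must be >= 1, got {sample_size}")
    if criterion == "caic":
        return -2.0 * log_likelihood + n_params * (math.log(sample_size) + 1.0)
    if criterion == "aic":
        return -2.0 * log_likelihood + 2.0 * n_params
    raise ValueError(f"unknown criterion {criterion!r}")


def select_feature_set(
    observations: Sequence[BatchObservation],
    space: MMISpace,
    *,
    criterion: str = "caic",
    sample_size_convention: str = "total_trials",
    full_output: bool = False,
) -> FeatureSpec | tuple[FeatureSpec, pd.DataFrame]:
    """Exhaustive quadratic-subset search minimising the selection criterion.

    Every candidate feature vector contains all linear terms plus one subset
    of the d(d+1)/2 quadratic terms; all 2^(d(d+1)/2) candidates are fitted
    to the pooled observations.  Ties are broken toward fewer terms, then
    lexicographically, so the result is independent of enumeration order.
    Individual fit failures skip that candidate with a warning.
    """
    if space.ndim > MAX_EXHAUSTIVE_AXES:
        raise ValueError(
            f"exhaustive search supports at most {MAX_EXHAUSTIVE_AXES} axes "
            f"({space.ndim} given); reduce the space or select manually"
        )
    quads = enumerate_quadratic_candidates(space)
    if sample_size_convention == "total_trials":
        sample_size = int(sum(o.n for o in observations))
    elif sample_size_convention == "n_sets":
        sample_size = len(observations)
    else:
        raise ValueError(f"unknown sample_size_convention {sample_size_convention!r}")

    candidates = []
    for r in range(len(quads) + 1):
        candidates.extend(combinations(quads, r))
    # tie-break order: fewer terms first, then lexicographic by term names
    candidates.sort(key=lambda subset: (len(subset), subset))

    rows = []
    best: tuple[float, FeatureSpec] | None = None
    for subset in candidates:
        spec = FeatureSpec.with_quadratics(space, subset)
        try:
            model = fit_lrm(observations, space, spec)
        except FitError as exc:
            warnings.warn(
                f"candidate {spec.names} skipped: {exc}", RuntimeWarning, stacklevel=2
            )
            continue
        score = caic(model.log_likelihood, len(spec) + 1, sample_size, criterion)
        rows.append(
            {
                "quadratic_terms": ";".join("*".join(t) for t in subset),
                "n_features": len(spec),
                "log_likelihood": model.log_likelihood,
                "criterion": score,
            }
        )
        if best is None or score < best[0]:
            best = (score, spec)
    if best is None:
        raise FitError("every candidate feature set failed to fit")
    table = pd.DataFrame(rows).sort_values("criterion", kind="stable").reset_index(drop=True)
    return (best[1], table) if full_output else best[1]


def run_two_iteration_pipeline(
    config: PipelineConfig, simulator: ToyModelConfig
) -> PipelineResult:
    """Full surrogate-building run against a (toy) stochastic simulator.

    Iteration 1: uniform MMI sets over the ROI, a batch of realizations per
    set, linear-features-only fit.  Iteration 2: transition-domain sets
    under that preliminary model, another round of batches.  Final model:
    criterion-selected quadratic features fitted on the pooled
    2 x sets_per_iteration observations.
    """
    space = config.space
    root = np.random.SeedSequence(config.seed)
    roi_ss, trans_ss, *batch_ss = root.spawn(2 + 2 * config.sets_per_iteration)

    def _simulate(points: np.ndarray, seeds) -> tuple[BatchObservation, ...]:
        return tuple(
            simulate_batch(simulator, pt, config.realizations_per_set, ss)
            for pt, ss in zip(points, seeds)
        )

    # --- iteration 1: uniform ROI sampling, linear-only fit
    try:
        pts1 = sample_roi(space, config.sets_per_iteration,
                          np.random.default_rng(roi_ss))
        obs1 = _simulate(pts1, batch_ss[: config.sets_per_iteration])
        model1 = fit_lrm(obs1, space, FeatureSpec.linear_only(space))
    except Exception as exc:
        raise PipelineStageError(f"iteration 1 (ROI sampling / linear fit): {exc}") from exc

    # --- iteration 2: transition-domain resampling under the preliminary model
    try:
        pts2 = sample_transition(
            space, model1, config.sets_per_iteration, config.transition_band,
            np.random.default_rng(trans_ss),
        )
        obs2 = _simulate(pts2, batch_ss[config.sets_per_iteration:])
        model2 = fit_lrm(obs1 + obs2, space, FeatureSpec.linear_only(space))
    except Exception as exc:
        raise PipelineStageError(f"iteration 2 (transition resampling): {exc}") from exc

    # --- final: exhaustive quadratic selection on the pooled observations
    try:
        pooled = obs1 + obs2
        spec, table = select_feature_set(
            pooled, space,
            criterion=config.criterion,
            sample_size_convention=config.sample_size_convention,
            full_output=True,
        )
        final = fit_lrm(pooled, space, spec)
        final = FittedLRM(
            space=final.space, spec=final.spec, intercept=final.intercept,
            weights=final.weights, se=final.se, intercept_se=final.intercept_se,
            log_likelihood=final.log_likelihood, n_obs=final.n_obs,
            provenance="fit", seed=config.seed,
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"final selection/fit: {exc}") from exc

    return PipelineResult(
        model=final,
        iterations=(
            IterationResult(obs1, model1, 1),
            IterationResult(obs2, model2, 2),
        ),
        selection_table=table,
        config=config,
    )
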