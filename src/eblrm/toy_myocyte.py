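"""Synthetic stochastic event simulator with a known probability surface.

Estimating an ectopic-beat probability from a spatially detailed stochastic
myocyte model costs tens of CPU hours per MMI set, which rules the real
simulator out for testing a surrogate-fitting pipeline end to end.  This
module provides a desk-scale stand-in: a seedable generator whose binary
event outcomes follow a *known* logistic-in-quadratic-features probability
surface over the MMI space, and whose per-realization output is a minimal
membrane-potential-like trace (resting potential approx. -93.4 mV) so that
the 0 mV event-detection rule is exercised exactly as it would be on real
voltage traces.

The waveforms are schematic placeholders, not physiology: an event trace
rises to a positive peak (an "action potential" crossing 0 mV), a non-event
trace to a subthreshold peak (a "delayed afterdepolarization" that stays
below 0 mV).  Only the detection threshold semantics are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .features import (
    ConfigurationError,
    FeatureSpec,
    MMISpace,
    expand_features,
    parse_term,
    scale_mmi,
)
from .lrm import BatchObservation, FittedLRM

__all__ = [
    "ToyModelConfig",
    "TraceOutcome",
    "true_probability",
    "simulate_realization",
    "simulate_batch",
    "detect_event",
]


@dataclass(frozen=True)
class ToyModelConfig:
    """Ground-truth surface and waveform parameters for the toy simulator.

    ``true_weights`` maps feature names ("ca_sr_ini", "ca_sr_ini^2",
    "g_k1_sf*k_ryr_sf", ...) to weights on [0, 1]-scaled features; together
    with ``true_intercept`` they define the true event probability
    logistic(b0 + B^T x) at any MMI point.
    """

    space: MMISpace
    true_intercept: float
    true_weights: dict[str, float]
    duration: float = 800.0  # ms
    rest_potential: float = -93.4  # mV
    event_peak: float = 35.0  # mV
    dad_peak_range: tuple[float, float] = (-80.0, -40.0)  # mV
    time_step: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.time_step <= 0 or self.time_step > self.duration:
            raise ConfigurationError("time_step must be in (0, duration]")
        if self.rest_potential >= 0:
            raise ConfigurationError("rest_potential must be below 0 mV")
        if self.event_peak <= 0:
            raise ConfigurationError("event_peak must exceed 0 mV")
        lo, hi = self.dad_peak_range
        if not (lo < hi < 0):
            raise ConfigurationError(
                "dad_peak_range must be an interval entirely below 0 mV"
            )
        # validates feature names against the space
        self.spec.validate_against(self.space)

    @property
    def spec(self) -> FeatureSpec:
        return FeatureSpec(tuple(parse_term(n) for n in self.true_weights))

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array(list(self.true_weights.values()), dtype=float)

    @classmethod
    def from_model(cls, model: FittedLRM, **kwargs) -> "ToyModelConfig":
        """Use a fitted/reconstructed surrogate as the ground-truth surface."""
        return cls(
            space=model.space,
            true_intercept=model.intercept,
            true_weights=dict(zip(model.spec.names, model.weights)),
            **kwargs,
        )


@dataclass(frozen=True)
class TraceOutcome:
    """One realization: a voltage trace and its binary event outcome."""

    times: np.ndarray  # ms
    voltages: np.ndarray  # mV
    event: bool


def true_probability(config: ToyModelConfig, point: np.ndarray) -> float | np.ndarray:
    """The simulator's exact event probability at an MMI point (no noise).

    Evaluates logistic(b0 + B^T x) on scaled features; extrapolation outside
    the space is allowed.
    """
    feats = expand_features(scale_mmi(point, config.space), config.spec, config.space)
    p = expit(config.true_intercept + feats @ config.weight_vector)
    return float(p) if np.ndim(p) == 0 else p


def detect_event(voltages: np.ndarray, threshold: float = 0.0) -> bool:
    """True iff any voltage sample strictly exceeds the threshold (default 0 mV)."""
    voltages = np.asarray(voltages, dtype=float)
    if voltages.size == 0:
        raise ValueError("voltage trace is empty")
    return bool(np.max(voltages) > threshold)


def _make_trace(config: ToyModelConfig, peak: float) -> TraceOutcome:
    # triangular rest -> peak -> rest; peak lands exactly on a grid sample
    times = np.arange(0.0, config.duration + config.time_step / 2, config.time_step)
    mid = len(times) // 2
    v = np.full_like(times, config.rest_potential)
    if mid > 0:
        v[: mid + 1] = np.linspace(config.rest_potential, peak, mid + 1)
        v[mid:] = np.linspace(peak, config.rest_potential, len(times) - mid)
    else:
        v[0] = config.rest_potential
    return TraceOutcome(times=times, voltages=v, event=detect_event(v))


def simulate_realization(
    config: ToyModelConfig, point: np.ndarray, rng: np.random.Generator
) -> TraceOutcome:
    """One stochastic realization: Bernoulli event draw plus a schematic trace."""
    p = true_probability(config, point)
    event = bool(rng.random() < p)
    if event:
        peak = config.event_peak
    else:
        lo, hi = config.dad_peak_range
        peak = float(rng.uniform(lo, hi))
    return _make_trace(config, peak)


def simulate_batch(
    config: ToyModelConfig,
    point: np.ndarray,
    n: int,
    seed: int | np.random.SeedSequence,
    *,
    return_traces: bool = False,
) -> BatchObservation | tuple[BatchObservation, list[TraceOutcome]]:
    """n realizations at one MMI point; returns the binomial count k of n.

    Event draws and waveform draws come from two named substreams spawned
    from one seed, so the event count is identical whether or not traces
    are materialised, and any (point, n, seed) triple is reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    event_ss, wave_ss = ss.spawn(2)
    p = true_probability(config, point)
    events = np.random.default_rng(event_ss).random(n) < p
    obs = BatchObservation(point=np.asarray(point, dtype=float),
                           k=int(events.sum()), n=n)
    if not return_traces:
        return obs
    wave_rng = np.random.default_rng(wave_ss)
    lo, hi = config.dad_peak_range
    traces = [
        _make_trace(config, config.event_peak if ev else float(wave_rng.uniform(lo, hi)))
        for ev in events
    ]
    return obs, traces
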