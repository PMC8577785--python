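"""Serialization: observation CSVs, model JSON, configs, curve/histogram exports.

Files carry native units (nM, uM, dimensionless); scaling to [0, 1] happens
only inside the feature layer.  Model JSON is schema-versioned and records
the frozen scaling bounds with the model, so a file round-trip reproduces
predictions bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .domains import MCCurve
from .features import Axis, FeatureSpec, MMISpace
from .lrm import BatchObservation, FittedLRM
from .pipeline import PipelineConfig
from .toy_myocyte import TraceOutcome
from .uncertainty import ProbabilityDistribution

__all__ = [
    "SchemaError",
    "write_observations_csv",
    "read_observations_csv",
    "write_model_json",
    "read_model_json",
    "write_trace_csv",
    "write_mc_curve_csv",
    "write_distribution",
    "load_pipeline_config",
]

MODEL_SCHEMA_VERSION = 1

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """Malformed serialized input; the message names the offending row/field."""


# ---- observations ----------------------------------------------------

def write_observations_csv(
    path: PathLike, observations: Sequence[BatchObservation], space: MMISpace
) -> None:
    """One row per MMI set: axis columns (native units), then k and n."""
    rows = [dict(zip(space.names, o.point)) | {"k": o.k, "n": o.n}
            for o in observations]
    pd.DataFrame(rows, columns=list(space.names) + ["k", "n"]).to_csv(path, index=False)


def read_observations_csv(path: PathLike, space: MMISpace) -> list[BatchObservation]:
    df = pd.read_csv(path)
    missing = [c for c in list(space.names) + ["k", "n"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                BatchObservation(
                    point=np.array([float(row[n]) for n in space.names]),
                    k=int(row["k"]),
                    n=int(row["n"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out


# ---- models ----------------------------------------------------------

def write_model_json(path: PathLike, model: FittedLRM) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "space": [
            {"name": a.name, "lo": a.lo, "hi": a.hi, "units": a.units}
            for a in model.space.axes
        ],
        "features": list(model.spec.names),
        "intercept": model.intercept,
        "weights": model.weights.tolist(),
        "se": None if model.se is None else model.se.tolist(),
        "intercept_se": model.intercept_se,
        "log_likelihood": model.log_likelihood,
        "n_obs": model.n_obs,
        "provenance": model.provenance,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_json(path: PathLike) -> FittedLRM:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("schema_version", "space", "features", "intercept", "weights"):
        if key not in doc:
            raise SchemaError(f"{path}: missing key {key!r}")
    if doc["schema_version"] != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version {doc['schema_version']} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        space = MMISpace(tuple(
            Axis(a["name"], a["lo"], a["hi"], a.get("units", "dimensionless"))
            for a in doc["space"]
        ))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed space entry: {exc}") from exc
    return FittedLRM(
        space=space,
        spec=FeatureSpec.from_names(doc["features"]),
        intercept=float(doc["intercept"]),
        weights=np.array(doc["weights"], dtype=float),
        se=None if doc.get("se") is None else np.array(doc["se"], dtype=float),
        intercept_se=doc.get("intercept_se"),
        log_likelihood=doc.get("log_likelihood"),
        n_obs=doc.get("n_obs"),
        provenance=doc.get("provenance", "fit"),
        seed=doc.get("seed"),
    )


# ---- traces, curves, distributions -----------------------------------

def write_trace_csv(path: PathLike, trace: TraceOutcome) -> None:
    pd.DataFrame({"time_ms": trace.times, "voltage_mV": trace.voltages}).to_csv(
        path, index=False
    )


def write_mc_curve_csv(path: PathLike, curve: MCCurve) -> None:
    pd.DataFrame({curve.axis: curve.grid, "probability": curve.probabilities}).to_csv(
        path, index=False
    )


def write_distribution(
    path_csv: PathLike, path_json: PathLike, dist: ProbabilityDistribution,
    extra: dict | None = None,
) -> None:
    """Histogram as CSV (bin edges + masses) plus a JSON summary."""
    pd.DataFrame(
        {
            "bin_lo": dist.bin_edges[:-1],
            "bin_hi": dist.bin_edges[1:],
            "mass": dist.masses,
        }
    ).to_csv(path_csv, index=False)
    from .uncertainty import classify_modality, entropy  # avoid cycle at import

    summary = {
        "mean": dist.mean,
        "sd": dist.sd,
        "entropy_nats": entropy(dist),
        "modality": classify_modality(dist),
        "n_samples": dist.n_samples,
        "analytic": dist.analytic,
    } | (extra or {})
    Path(path_json).write_text(json.dumps(summary, indent=2))


# ---- configs ---------------------------------------------------------

def load_pipeline_config(path: PathLike) -> PipelineConfig:
    """Pipeline config from YAML or JSON; errors name the missing key."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    if "space" not in doc:
        raise SchemaError(f"{path}: missing key 'space'")
    axes = []
    for i, a in enumerate(doc["space"]):
        for key in ("name", "lo", "hi"):
            if key not in a:
                raise SchemaError(f"{path}: space[{i}]: missing key {key!r}")
        axes.append(Axis(a["name"], float(a["lo"]), float(a["hi"]),
                         a.get("units", "dimensionless")))
    kwargs = {
        k: doc[k]
        for k in (
            "sets_per_iteration", "realizations_per_set", "criterion",
            "sample_size_convention", "seed",
        )
        if k in doc
    }
    if "transition_band" in doc:
        band = doc["transition_band"]
        if not (isinstance(band, (list, tuple)) and len(band) == 2):
            raise SchemaError(f"{path}: transition_band must be [lo, hi]")
        kwargs["transition_band"] = (float(band[0]), float(band[1]))
    try:
        return PipelineConfig(space=MMISpace(tuple(axes)), **kwargs)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
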