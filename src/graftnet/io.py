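"""Readers and writers for the plain-text data interchange formats.

Time-course tables are delimited text (CSV by default) with a ``time_days``
column; parameter bundles are JSON with a versioned schema.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    CLUSTER_LABELS,
    CNParameters,
    CellEventSeries,
    ClusterExpressionSeries,
    ScalingFactors,
    TherapySpec,
    TimeGrid,
    VesselState,
    WeightVector,
)

SCHEMA_VERSION = 1

TIME_COL = "time_days"

EVENT_COLS = {"mitosis_rate": "mitosis", "apoptosis_rate": "apoptosis", "ecm_rate": "ecm"}
MORPHOLOGY_COLS = ("intimal_thickness_mm", "intimal_area_mm2", "lumen_radius_mm")


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if TIME_COL not in df.columns:
        raise ValueError(f"{path}: missing required column {TIME_COL!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(f"{path}: non-numeric cells in column {col!r}: {list(bad)[:3]}")
    return df


def _align_grid(df: pd.DataFrame, grid: TimeGrid, path) -> pd.DataFrame:
    t = df[TIME_COL].to_numpy(dtype=float)
    order = np.argsort(t)
    df = df.iloc[order]
    t = t[order]
    missing = [g for g in grid.times if not np.any(np.isclose(t, g, atol=1e-6))]
    if missing:
        raise ValueError(f"{path}: missing time points (days): {missing}")
    keep = [int(np.argmin(np.abs(t - g))) for g in grid.times]
    return df.iloc[keep]


def read_timecourse_table(path, schema_id: str, *, network_id: str = "MIT",
                          grid: TimeGrid | None = None):
    """Read one study-shaped table.

    ``schema_id`` selects the layout: ``"expression"`` (columns A..E) returns a
    :class:`ClusterExpressionSeries` for ``network_id``; ``"events"`` returns a
    :class:`CellEventSeries`; ``"morphology"`` returns a DataFrame with the
    intimal thickness/area and lumen radius columns. Unknown columns are
    tolerated and reported in the returned object's ``attrs`` where applicable.
    """
    grid = grid or TimeGrid()
    df = _align_grid(_read_table(path), grid, path)

    if schema_id == "expression":
        if len(set(df.columns)) != len(df.columns):
            raise ValueError(f"{path}: duplicate column labels")
        missing = [c for c in CLUSTER_LABELS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing cluster columns {missing}")
        values = df[list(CLUSTER_LABELS)].to_numpy(dtype=float).T
        return ClusterExpressionSeries(network_id=network_id, values=values, grid=grid)

    if schema_id == "events":
        missing = [c for c in EVENT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing event columns {missing}")
        return CellEventSeries(
            mitosis=df["mitosis_rate"].to_numpy(dtype=float),
            apoptosis=df["apoptosis_rate"].to_numpy(dtype=float),
            ecm=df["ecm_rate"].to_numpy(dtype=float),
            grid=grid,
        )

    if schema_id == "morphology":
        missing = [c for c in MORPHOLOGY_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing morphology columns {missing}")
        out = df[[TIME_COL, *MORPHOLOGY_COLS]].reset_index(drop=True)
        out.attrs["unknown_columns"] = [
            c for c in df.columns if c not in (TIME_COL, *MORPHOLOGY_COLS)
        ]
        return out

    raise ValueError(f"unknown schema_id {schema_id!r}")


def write_expression(series: ClusterExpressionSeries, path) -> None:
    df = pd.DataFrame({TIME_COL: series.grid.times})
    for i, label in enumerate(CLUSTER_LABELS):
        df[label] = series.values[i]
    df.to_csv(path, index=False, float_format="%.17g")


def write_events(events: CellEventSeries, path) -> None:
    df = pd.DataFrame({TIME_COL: events.grid.times})
    for col, attr in EVENT_COLS.items():
        df[col] = getattr(events, attr)
    df.to_csv(path, index=False, float_format="%.17g")


def write_morphology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# JSON parameter bundles


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def save_params(obj: Any, path, kind: str) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "kind": kind, "data": _to_jsonable(obj)}
    Path(path).write_text(json.dumps(payload, indent=2))


def _load(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version")
    return payload


def load_cn_parameters(path) -> CNParameters:
    d = _load(path)["data"]
    return CNParameters(A=np.asarray(d["A"]), B=np.asarray(d["B"]), C=np.asarray(d["C"]))


def load_weight_vector(path) -> WeightVector:
    d = _load(path)["data"]
    return WeightVector(network_id=d["network_id"], w=np.asarray(d["w"]))


def load_scaling_factors(path) -> ScalingFactors:
    d = _load(path)["data"]
    return ScalingFactors(
        beta_mit=np.asarray(d["beta_mit"]),
        beta_apop=np.asarray(d["beta_apop"]),
        beta_ecm=np.asarray(d["beta_ecm"]),
    )


def load_therapy_spec(path) -> TherapySpec:
    d = _load(path)["data"]
    return TherapySpec(deltas=d["deltas"])


def save_hybrid_parameters(params, path) -> None:
    from .hybrid import HybridParameters  # local import to avoid a cycle

    assert isinstance(params, HybridParameters)
    save_params(params, path, kind="HybridParameters")


def load_hybrid_parameters(path):
    from .hybrid import HybridParameters

    d = _load(path)["data"]
    cn = {k: CNParameters(A=np.asarray(v["A"]), B=np.asarray(v["B"]), C=np.asarray(v["C"]))
          for k, v in d["cn"].items()}
    g0 = {k: np.asarray(v, dtype=float) for k, v in d["g0"].items()}
    weights = {k: WeightVector(network_id=v["network_id"], w=np.asarray(v["w"]))
               for k, v in d["weights"].items()}
    scaling = ScalingFactors(
        beta_mit=np.asarray(d["scaling"]["beta_mit"]),
        beta_apop=np.asarray(d["scaling"]["beta_apop"]),
        beta_ecm=np.asarray(d["scaling"]["beta_ecm"]),
    )
    scenario = VesselState(**{k: v for k, v in d["scenario"].items()})
    return HybridParameters(cn=cn, g0=g0, weights=weights, scaling=scaling, scenario=scenario)


def load_scenario_yaml(path) -> VesselState:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return VesselState(**cfg)
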