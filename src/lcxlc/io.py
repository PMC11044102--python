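"""File formats: analyte tables, configuration files, injection profiles.

Analyte CSV schema (one row per analyte; units: retention parameters
dimensionless, van Deemter a in µm, b in µm·mm/s, c in µm·s/mm):

    name, d1_kind, d1_p1, d1_p2, d1_vd_a, d1_vd_b, d1_vd_c,
          d2_kind, d2_p1, d2_p2, d2_vd_a, d2_vd_b, d2_vd_c

``*_kind`` is ``lss`` (p1 = k0, p2 = S) or ``adsorption`` (p1 = k100,
p2 = n).  Parsing is strict: unknown columns are rejected and malformed
rows are reported with row number and field.

Configuration files are YAML with an ``instrument`` block (dwell
volumes, extra-column variances, pressure limits, loop inventory) and a
``ranges`` block (candidate lists).  Flows may be given in mL/min using
a ``_ml_min`` suffix on the key; they are converted to µL/min at parse
time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .craig import InjectionProfile
from .metrics import Column, InstrumentLimits
from .optimizer import GradientSpec, ParameterRanges
from .retention import Analyte, RetentionModel, VanDeemterCurve

__all__ = [
    "ANALYTE_COLUMNS",
    "load_analytes",
    "save_analytes",
    "load_config",
    "load_injection_profile",
]

ANALYTE_COLUMNS = [
    "name",
    "d1_kind", "d1_p1", "d1_p2", "d1_vd_a", "d1_vd_b", "d1_vd_c",
    "d2_kind", "d2_p1", "d2_p2", "d2_vd_a", "d2_vd_b", "d2_vd_c",
]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def load_analytes(path) -> list[Analyte]:
    """Read and validate an analyte parameter CSV."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    unknown = set(df.columns) - set(ANALYTE_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    missing = set(ANALYTE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    analytes = []
    for i, row in df.iterrows():
        try:
            models = {}
            curves = {}
            for dim in ("d1", "d2"):
                kind = str(row[f"{dim}_kind"])
                if kind not in ("lss", "adsorption"):
                    raise ValueError(f"field {dim}_kind: unknown kind {kind!r}")
                models[dim] = RetentionModel(kind, float(row[f"{dim}_p1"]), float(row[f"{dim}_p2"]))
                curves[dim] = VanDeemterCurve(
                    float(row[f"{dim}_vd_a"]), float(row[f"{dim}_vd_b"]), float(row[f"{dim}_vd_c"])
                )
            analytes.append(
                Analyte(
                    name=str(row["name"]),
                    model_d1=models["d1"], model_d2=models["d2"],
                    vd_d1=curves["d1"], vd_d2=curves["d2"],
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {i + 2}: {exc}") from exc  # +2: header + 1-based
    return analytes


def save_analytes(analytes, path) -> None:
    """Write an analyte list as the documented CSV schema."""
    rows = []
    for a in analytes:
        rows.append(
            {
                "name": a.name,
                "d1_kind": a.model_d1.kind, "d1_p1": a.model_d1.p1, "d1_p2": a.model_d1.p2,
                "d1_vd_a": a.vd_d1.a, "d1_vd_b": a.vd_d1.b, "d1_vd_c": a.vd_d1.c,
                "d2_kind": a.model_d2.kind, "d2_p1": a.model_d2.p1, "d2_p2": a.model_d2.p2,
                "d2_vd_a": a.vd_d2.a, "d2_vd_b": a.vd_d2.b, "d2_vd_c": a.vd_d2.c,
            }
        )
    pd.DataFrame(rows, columns=ANALYTE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def _flow_list(block: dict, key: str) -> list[float]:
    """Candidate flow list; a ``<key>_ml_min`` variant is converted to µL/min."""
    if key in block:
        return [float(v) for v in block[key]]
    ml_key = f"{key}_ml_min"
    if ml_key in block:
        return [float(v) * 1000.0 for v in block[ml_key]]
    raise SchemaError(f"ranges block needs {key} or {ml_key}")


def _column(block: dict) -> Column:
    try:
        return Column(
            length=float(block["length_mm"]),
            internal_diameter=float(block["id_mm"]),
            dp=float(block["dp_um"]),
            porosity=float(block["porosity"]),
            flow_resistance=float(block.get("flow_resistance", 700.0)),
            max_pressure=float(block.get("max_pressure_bar", 1000.0)),
        )
    except KeyError as exc:
        raise SchemaError(f"column block missing field {exc}") from exc


def _gradients(entries) -> list[GradientSpec]:
    return [
        GradientSpec(float(e["phi_init"]), float(e["phi_final"]), float(e["t_grad_min"]))
        for e in entries
    ]


def load_config(path) -> ParameterRanges:
    """Parse a YAML optimization-range + instrument configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ranges" not in doc:
        raise SchemaError("config must contain a 'ranges' mapping")
    ranges = doc["ranges"]
    instrument = doc.get("instrument", {})
    limits = InstrumentLimits(
        max_pressure_d1=float(instrument.get("max_pressure_d1_bar", 1000.0)),
        max_pressure_d2=float(instrument.get("max_pressure_d2_bar", 1300.0)),
        extra_column_variance_d1=float(instrument.get("extra_column_variance_d1_ul2", 17.0)),
        extra_column_variance_d2=float(instrument.get("extra_column_variance_d2_ul2", 3.8)),
        reequilibration_time=float(instrument.get("reequilibration_time_min", 0.1)),
        sample_volume_d1=float(instrument.get("sample_volume_d1_ul", 1.0)),
    )
    g2 = ranges.get("gradients_d2")
    return ParameterRanges(
        column_d1=_column(ranges["column_d1"]),
        column_d2=_column(ranges["column_d2"]),
        flows_d1=_flow_list(ranges, "flows_d1"),
        flows_d2=_flow_list(ranges, "flows_d2"),
        sampling_times=[float(v) for v in ranges["sampling_times_min"]],
        makeup_flows=_flow_list(ranges, "makeup_flows"),
        loop_volumes=[float(v) for v in ranges["loop_volumes_ul"]],
        gradients_d1=_gradients(ranges["gradients_d1"]),
        gradients_d2=_gradients(g2) if g2 else None,
        dwell_volume_d1=float(instrument.get("dwell_volume_d1_ul", 13.0)),
        dwell_volume_d2=float(instrument.get("dwell_volume_d2_ul", 55.0)),
        makeup_composition=float(ranges.get("makeup_composition", 0.0)),
        limits=limits,
        temperature_d1=float(ranges.get("temperature_d1", 30.0)),
        temperature_d2=float(ranges.get("temperature_d2", 60.0)),
    )


def load_injection_profile(path, flow: float | None = None) -> InjectionProfile:
    """Import a measured valve injection profile.

    CSV columns: ``time_min, relative_concentration[, phi_ss]``.  The
    concentration track is renormalized to unit mass; a missing solvent
    track defaults to zero strong solvent.
    """
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "relative_concentration"}
    if not required <= set(df.columns):
        raise SchemaError(f"injection profile needs columns {sorted(required)}")
    t = df["time_min"].to_numpy(dtype=float)
    if len(t) < 2 or not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-6):
        raise SchemaError("time grid must be uniform with >= 2 points")
    c = df["relative_concentration"].to_numpy(dtype=float)
    if np.any(c < 0):
        raise SchemaError("relative_concentration must be non-negative")
    dt = float(t[1] - t[0])
    c = c / (c.sum() * dt)
    phi = (
        df["phi_ss"].to_numpy(dtype=float)
        if "phi_ss" in df.columns
        else np.zeros_like(c)
    )
    return InjectionProfile(time=t - t[0], concentration=c, phi=phi)
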