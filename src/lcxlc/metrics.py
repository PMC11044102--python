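"""Theoretical performance descriptors for one LC x LC configuration.

Everything needed to score a candidate method without running the Craig
simulator lives here: injection variance under solvent mismatch, peak
widths, per-dimension and two-dimensional peak capacity with
undersampling and last-peak window corrections, dilution factors,
modulation-valve geometry (loop filling) and Darcy pressure feasibility.

Units are normalized throughout: min, µL, µL/min, mm (column length and
bore), µm (particle size, plate height), bar, mPa·s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .retention import GradientProgram, VanDeemterCurve, plate_count

__all__ = [
    "Column",
    "ColumnState",
    "ModulationSettings",
    "InjectionContext",
    "InstrumentLimits",
    "ExperimentalConfig",
    "PerformanceMetrics",
    "InfeasibleConfigError",
    "column_state",
    "injection_variance",
    "sample_solvent_composition",
    "modulation_geometry",
    "column_variance_gradient",
    "total_peak_variance",
    "undersampling_factor",
    "dimension_peak_capacity",
    "two_dimensional_peak_capacity",
    "dilution_factor",
    "pressure_drop",
    "viscosity_water_acn",
]


class InfeasibleConfigError(ValueError):
    """A candidate configuration violates a hard instrument constraint."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Column:
    """Packed column geometry and limits.

    length and internal diameter in mm, particle size ``dp`` in µm,
    total porosity ``porosity`` (dimensionless), dimensionless flow
    resistance ``flow_resistance`` and maximum operating pressure in bar.
    """

    length: float
    internal_diameter: float
    dp: float
    porosity: float
    flow_resistance: float = 700.0
    max_pressure: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.length, self.internal_diameter, self.dp, self.flow_resistance,
               self.max_pressure) <= 0:
            raise ValueError("column parameters must be positive")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")

    @property
    def void_volume(self) -> float:
        """Void volume in µL (mm^3 == µL)."""
        return self.porosity * math.pi * (self.internal_diameter / 2.0) ** 2 * self.length


class ColumnState(NamedTuple):
    """Column operating point at one flow rate."""

    n_plates: float
    t0: float  # min
    v0: float  # µL
    u: float  # mm/s


def column_state(column: Column, vd: VanDeemterCurve, flow: float) -> ColumnState:
    """Operating state (N, t0, V0, u) of ``column`` at ``flow`` µL/min."""
    if flow <= 0:
        raise ValueError("flow must be positive")
    v0 = column.void_volume
    t0 = v0 / flow  # min
    u = column.length / (t0 * 60.0)  # mm/s
    n = plate_count(vd, u, column.length)
    return ColumnState(n_plates=n, t0=t0, v0=v0, u=u)


@dataclass(frozen=True)
class ModulationSettings:
    """Interface between the two dimensions.

    sampling_time in min, makeup_flow in µL/min, loop_volume in µL;
    makeup_composition is expressed in the second dimension's
    strong-solvent convention.
    """

    sampling_time: float
    makeup_flow: float
    loop_volume: float
    makeup_composition: float = 0.0
    valve_mode: str = "counter-current"

    def __post_init__(self) -> None:
        if self.sampling_time <= 0 or self.loop_volume <= 0:
            raise ValueError("sampling time and loop volume must be positive")
        if self.makeup_flow < 0:
            raise ValueError("makeup flow must be non-negative")
        if not 0.0 <= self.makeup_composition <= 1.0:
            raise ValueError("makeup composition must lie in [0, 1]")
        if self.valve_mode not in ("counter-current", "co-current"):
            raise ValueError(f"unknown valve mode {self.valve_mode!r}")


@dataclass(frozen=True)
class InjectionContext:
    """Inputs to the injection-variance equation."""

    v_inj: float  # µL
    flow: float  # µL/min
    k_e: float
    k_ss: float
    delta_sq: float = 8.0

    def __post_init__(self) -> None:
        if self.v_inj < 0 or self.k_e < 0 or self.k_ss < 0:
            raise ValueError("v_inj, k_e, k_ss must be non-negative")
        if self.flow <= 0 or self.delta_sq <= 0:
            raise ValueError("flow and delta_sq must be positive")


@dataclass(frozen=True)
class InstrumentLimits:
    """System-level constraints and extra-column contributions.

    Extra-column variances in µL² (defaults: 17 after the valve is
    nullified by focusing and only the post-column 3.8 is counted in the
    second dimension; the first-dimension value covers the autosampler
    path).
    """

    max_pressure_d1: float = 1000.0  # bar
    max_pressure_d2: float = 1300.0  # bar
    extra_column_variance_d1: float = 17.0  # µL²
    extra_column_variance_d2: float = 3.8  # µL²
    reequilibration_time: float = 0.1  # min, ²D cycle overhead
    sample_volume_d1: float = 1.0  # µL injected on the ¹D column


@dataclass(frozen=True)
class ExperimentalConfig:
    """One complete candidate LC x LC method."""

    column_d1: Column
    gradient_d1: GradientProgram
    column_d2: Column
    gradient_d2: GradientProgram
    modulation: ModulationSettings
    limits: InstrumentLimits = field(default_factory=InstrumentLimits)

    @property
    def flow_d1(self) -> float:
        return self.gradient_d1.flow

    @property
    def flow_d2(self) -> float:
        return self.gradient_d2.flow


@dataclass(frozen=True)
class PerformanceMetrics:
    """The three Pareto objectives plus their per-dimension components."""

    n1c_corrected: float
    n2c: float
    nc_2d: float
    analysis_time: float  # min
    dilution_total: float  # fold
    n1c_raw: float = math.nan
    undersampling_beta: float = math.nan

    def objectives(self) -> tuple[float, float, float]:
        """(nc_2d, analysis_time, dilution_total) — max, min, min."""
        return (self.nc_2d, self.analysis_time, self.dilution_total)


# ---------------------------------------------------------------------------
# Injection and transfer
# ---------------------------------------------------------------------------


def injection_variance(ctx: InjectionContext) -> tuple[float, float]:
    """Variance of the sample plug due to the injection process.

    Returns ``(sigma_v_sq, sigma_t_sq)`` in µL² and min².  The volume
    variance is ``(V_inj²/δ_inj²)·((1+k_e)/(1+k_ss))²``: a sample solvent
    stronger than the mobile phase (k_ss < k_e) inflates the band, a
    weaker one focuses it.
    """
    ratio = (1.0 + ctx.k_e) / (1.0 + ctx.k_ss)
    sigma_v_sq = (ctx.v_inj**2 / ctx.delta_sq) * ratio**2
    return sigma_v_sq, sigma_v_sq / ctx.flow**2


def sample_solvent_composition(
    phi1_at_transfer: float, f1: float, f_mu: float, makeup_comp: float = 0.0
) -> float:
    """Second-dimension sample-solvent composition after make-up dilution.

    The ¹D effluent composition is first converted to the ²D
    strong-solvent convention (the dimensions' strong solvents are
    opposite, e.g. HILIC->RP: ²D-strong fraction = 1 - phi1) and then
    volume-blended with the make-up flow.
    """
    if f1 <= 0 or f_mu < 0:
        raise ValueError("flows must be positive (f1) / non-negative (f_mu)")
    return (f1 * (1.0 - phi1_at_transfer) + f_mu * makeup_comp) / (f1 + f_mu)


class ModulationGeometry(NamedTuple):
    eluent_fraction_volume: float  # µL of ¹D effluent per modulation
    total_fraction_volume: float  # µL including make-up
    fill_fraction: float  # of the loop


def modulation_geometry(
    f1: float, f_mu: float, ts: float, loop_volume: float
) -> ModulationGeometry:
    """Loop-filling geometry for one modulation period.

    Raises :class:`InfeasibleConfigError` when the transferred volume
    exceeds the loop.
    """
    if min(f1, ts, loop_volume) <= 0 or f_mu < 0:
        raise ValueError("inputs must be positive (f_mu may be zero)")
    eluent = f1 * ts
    total = (f1 + f_mu) * ts
    fill = total / loop_volume
    if fill > 1.0 + 1e-12:
        raise InfeasibleConfigError(
            f"fraction volume {total:.4g} µL exceeds loop volume {loop_volume:.4g} µL"
        )
    return ModulationGeometry(eluent, total, min(fill, 1.0))


# ---------------------------------------------------------------------------
# Peak widths and capacities
# ---------------------------------------------------------------------------


def column_variance_gradient(state: ColumnState, k_e: float, compression: float = 1.0) -> float:
    """Column band-broadening time variance (min²) at elution.

    sigma = G * t0 * (1 + k_e) / sqrt(N); the gradient compression
    factor G defaults to 1 (off) and may be set in (0, 1].
    """
    if state.n_plates < 1:
        raise ValueError("plate count must be >= 1")
    if not 0.0 < compression <= 1.0:
        raise ValueError("compression factor must lie in (0, 1]")
    sigma = compression * state.t0 * (1.0 + k_e) / math.sqrt(state.n_plates)
    return sigma**2


def total_peak_variance(column_var: float, injection_var: float, extra_column_var: float) -> float:
    """Additive combination of independent variance contributions."""
    if min(column_var, injection_var, extra_column_var) < 0:
        raise ValueError("variances must be non-negative")
    return column_var + injection_var + extra_column_var


def undersampling_factor(ts: float, sigma1: float) -> float:
    """First-dimension undersampling (band-remixing) factor beta >= 1.

    beta = sqrt(1 + 0.21 (ts/sigma1)^2); the corrected peak capacity is
    the raw one divided by beta.
    """
    if ts <= 0 or sigma1 <= 0:
        raise ValueError("ts and sigma1 must be positive")
    return math.sqrt(1.0 + 0.21 * (ts / sigma1) ** 2)


def dimension_peak_capacity(window: tuple[float, float], mean_peak_sigma: float) -> float:
    """Peak capacity of one dimension over ``window = (t_first, t_last)``.

    n_c = 1 + (t_last - t_first) / (4 sigma), with the window ending at
    the predicted last-eluting analyte rather than the programmed
    gradient end.
    """
    t_first, t_last = window
    if t_last < t_first:
        raise ValueError("window must satisfy t_last >= t_first")
    if mean_peak_sigma <= 0:
        raise ValueError("mean peak sigma must be positive")
    return 1.0 + (t_last - t_first) / (4.0 * mean_peak_sigma)


def two_dimensional_peak_capacity(n1c_corrected: float, n2c: float) -> float:
    """Product rule n_c,2D = ¹n'_c × ²n_c (full-coverage assumption)."""
    if n1c_corrected < 1 or n2c < 1:
        raise ValueError("peak capacities must be >= 1")
    return n1c_corrected * n2c


def dilution_factor(
    sigma_v_d1: Sequence[float],
    v_inj_d1: float,
    sigma_v_d2: Sequence[float],
    v_inj_d2: Sequence[float],
    f1: float,
    f_mu: float,
) -> float:
    """Average total dilution across both dimensions and the make-up tee.

    Per analyte: DF = DF1 * DF_mu * DF2 with DF_i the peak-maximum
    dilution ``sqrt(2π)·σ_v,i / V_inj,i`` (volume units) and
    ``DF_mu = (F1+Fmu)/F1``; the arithmetic mean over analytes is
    returned.
    """
    s1 = np.asarray(sigma_v_d1, dtype=float)
    s2 = np.asarray(sigma_v_d2, dtype=float)
    v2 = np.asarray(v_inj_d2, dtype=float)
    if s1.shape != s2.shape or s1.shape != v2.shape:
        raise ValueError("per-analyte arrays must have matching lengths")
    if v_inj_d1 <= 0 or np.any(v2 <= 0):
        raise ValueError("injected volumes must be positive")
    df_mu = (f1 + f_mu) / f1
    root_2pi = math.sqrt(2.0 * math.pi)
    df = (root_2pi * s1 / v_inj_d1) * df_mu * (root_2pi * s2 / v2)
    return float(np.mean(df))


# ---------------------------------------------------------------------------
# Pressure feasibility
# ---------------------------------------------------------------------------

# Shipped default viscosity table for water/acetonitrile mixtures (mPa·s)
# vs ACN volume fraction, at 30 and 60 °C; linear interpolation between
# nodes and between the two temperatures.
_VISC_PHI = np.linspace(0.0, 1.0, 11)
_VISC_30C = np.array([0.80, 0.91, 0.98, 0.99, 0.96, 0.89, 0.79, 0.68, 0.57, 0.46, 0.35])
_VISC_60C = np.array([0.47, 0.54, 0.58, 0.59, 0.57, 0.53, 0.48, 0.42, 0.36, 0.31, 0.26])


def viscosity_water_acn(phi_acn, temperature: float = 30.0):
    """Viscosity (mPa·s) of a water/acetonitrile mixture.

    Linear interpolation in the shipped node table over ACN fraction and
    temperature (nodes at 30 and 60 °C, clamped outside).
    """
    phi = np.clip(np.asarray(phi_acn, dtype=float), 0.0, 1.0)
    w = np.clip((temperature - 30.0) / 30.0, 0.0, 1.0)
    eta = (1.0 - w) * np.interp(phi, _VISC_PHI, _VISC_30C) + w * np.interp(
        phi, _VISC_PHI, _VISC_60C
    )
    return float(eta) if np.isscalar(phi_acn) else eta


def pressure_drop(column: Column, flow: float, viscosity: float) -> float:
    """Darcy pressure drop across ``column`` in bar.

    ΔP = φ_res · η · L · u / dp² with η in mPa·s, L in mm, u in mm/s and
    dp in µm; the unit bookkeeping collapses to a factor 10^-2 into bar
    (10^3 into Pa, divided by 10^5 Pa/bar).  ``u`` is the chromatographic
    linear velocity derived from the total porosity.
    """
    if flow <= 0 or viscosity <= 0:
        raise ValueError("flow and viscosity must be positive")
    t0_min = column.void_volume / flow
    u = column.length / (t0_min * 60.0)  # mm/s
    return column.flow_resistance * viscosity * column.length * u / column.dp**2 * 1e-2
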