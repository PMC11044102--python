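"""Configuration enumeration, evaluation and hybrid Pareto optimization.

The optimization proceeds over the Cartesian product of candidate
parameter values (flows, sampling times, make-up flows, loop volumes,
gradients), filtered by hard instrument constraints (pressure in both
dimensions, loop capacity, second-dimension cycle time).  Each feasible
configuration is scored on three objectives: two-dimensional peak
capacity (maximize), analysis time and total dilution (minimize).

Two evaluation routes exist.  The *theoretical* route prices the
second-dimension injection broadening with the injection-variance
equation; the *simulated* route replaces the second-dimension retention
time and peak width with the apex and second-moment sigma of a Craig
simulation, which additionally yields split-peak diagnostics and true
elution profiles.  Because one simulation costs at least one calculation
per theoretical plate, the hybrid algorithm runs the cheap theoretical
route over the whole grid, keeps its Pareto front, re-evaluates *only
those* configurations with the simulator, and re-applies Pareto
filtering — configurations whose simulated performance drops below a
neighbor's are removed from the final front.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .craig import (
    CraigColumn,
    ElutionProfile,
    make_injection_profile,
    profile_moments,
    simulate_elution,
)
from .metrics import (
    Column,
    ExperimentalConfig,
    InfeasibleConfigError,
    InjectionContext,
    InstrumentLimits,
    ModulationSettings,
    PerformanceMetrics,
    column_state,
    column_variance_gradient,
    dilution_factor,
    dimension_peak_capacity,
    injection_variance,
    modulation_geometry,
    pressure_drop,
    sample_solvent_composition,
    total_peak_variance,
    two_dimensional_peak_capacity,
    undersampling_factor,
    viscosity_water_acn,
)
from .retention import (
    Analyte,
    GradientProgram,
    RetentionModel,
    composition_at_inlet,
    local_k_at_elution,
    predict_gradient_retention,
    retention_factor,
)

__all__ = [
    "GradientSpec",
    "ParameterRanges",
    "PerAnalyteDetail",
    "ParetoPoint",
    "HybridResult",
    "enumerate_feasible_configs",
    "evaluate_config_theoretical",
    "evaluate_config_simulated",
    "pareto_front",
    "hybrid_optimize",
    "full_simulation_optimize",
    "front_to_dataframe",
    "config_from_row",
]

_PHI_MIN = 1e-9


@dataclass(frozen=True)
class GradientSpec:
    """Candidate gradient: span and duration (flow supplied separately)."""

    phi_init: float
    phi_final: float
    t_grad: float  # min


@dataclass(frozen=True)
class ParameterRanges:
    """Candidate experimental values and the fixed hardware they run on."""

    column_d1: Column
    column_d2: Column
    flows_d1: Sequence[float]  # µL/min
    flows_d2: Sequence[float]  # µL/min
    sampling_times: Sequence[float]  # min
    makeup_flows: Sequence[float]  # µL/min
    loop_volumes: Sequence[float]  # µL
    gradients_d1: Sequence[GradientSpec]
    gradients_d2: Sequence[GradientSpec] | None = None  # None: fill the cycle
    dwell_volume_d1: float = 13.0  # µL
    dwell_volume_d2: float = 55.0  # µL
    makeup_composition: float = 0.0  # ²D convention
    limits: InstrumentLimits = field(default_factory=InstrumentLimits)
    d1_strong_is_acn: bool = False  # HILIC first dimension: strong solvent is water
    d2_strong_is_acn: bool = True  # RP second dimension: strong solvent is ACN
    temperature_d1: float = 30.0  # °C, for viscosity lookup
    temperature_d2: float = 60.0
    d2_span_default: tuple[float, float] = (0.01, 0.55)

    def __post_init__(self) -> None:
        for name in ("flows_d1", "flows_d2", "sampling_times", "makeup_flows", "loop_volumes"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(v <= 0 for v in vals) and name != "makeup_flows":
                raise ValueError(f"{name} values must be positive")
            if name == "makeup_flows" and any(v < 0 for v in vals):
                raise ValueError("makeup flows must be non-negative")
        if len(self.gradients_d1) == 0:
            raise ValueError("gradients_d1 must be non-empty")


@dataclass
class PerAnalyteDetail:
    """Evaluation trace for one analyte under one configuration."""

    name: str
    eluted: bool
    t_r1: float = math.nan
    sigma1: float = math.nan  # min
    fraction_index: int = -1
    phi1: float = math.nan  # ¹D exit composition at transfer (¹D convention)
    phi_ss: float = math.nan  # sample solvent (²D convention)
    v_inj: float = math.nan  # µL onto ²D
    t_r2: float = math.nan
    sigma2: float = math.nan  # min
    k_e2: float = math.nan
    k_ss: float = math.nan
    n_maxima: int = 1
    profile: ElutionProfile | None = None


@dataclass
class ParetoPoint:
    """One configuration with its metrics and evaluation provenance."""

    config: ExperimentalConfig
    metrics: PerformanceMetrics
    evaluation: str  # "theoretical" | "simulated"
    detail: list[PerAnalyteDetail] = field(default_factory=list)


@dataclass
class HybridResult:
    """Output of the two-stage (theory then simulation) optimization."""

    preliminary_front: list[ParetoPoint]
    refined_front: list[ParetoPoint]
    removed: list[ParetoPoint]  # simulated points dominated at the final stage
    simulation_count: int
    n_configs: int
    n_feasible: int


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def _eta_max(span: tuple[float, float], strong_is_acn: bool, temperature: float) -> float:
    """Worst-case viscosity over a gradient's composition span."""
    phis = np.linspace(min(span), max(span), 21)
    phi_acn = phis if strong_is_acn else 1.0 - phis
    return float(np.max(viscosity_water_acn(phi_acn, temperature)))


def enumerate_feasible_configs(ranges: ParameterRanges) -> list[ExperimentalConfig]:
    """All candidate combinations that satisfy the hard constraints.

    Constraints: Darcy pressure within column and instrument limits in
    both dimensions (worst-case viscosity over the gradient span), the
    transferred fraction fitting the loop, and the second-dimension
    cycle closing (``ts >= t_grad2 + re-equilibration``).  Raises with
    per-constraint rejection counts if nothing survives.
    """
    limits = ranges.limits
    rejected = {"pressure_d1": 0, "pressure_d2": 0, "loop": 0, "cycle": 0}
    configs: list[ExperimentalConfig] = []

    for g1_spec, f1 in itertools.product(ranges.gradients_d1, ranges.flows_d1):
        eta1 = _eta_max((g1_spec.phi_init, g1_spec.phi_final), ranges.d1_strong_is_acn,
                        ranges.temperature_d1)
        dp1 = pressure_drop(ranges.column_d1, f1, eta1)
        p1_ok = dp1 <= min(ranges.column_d1.max_pressure, limits.max_pressure_d1)
        for f2, ts, f_mu, loop in itertools.product(
            ranges.flows_d2, ranges.sampling_times, ranges.makeup_flows, ranges.loop_volumes
        ):
            if ranges.gradients_d2 is None:
                t2 = ts - limits.reequilibration_time
                g2_candidates = (
                    [GradientSpec(*ranges.d2_span_default, t2)] if t2 > 0 else []
                )
            else:
                g2_candidates = list(ranges.gradients_d2)
            for g2_spec in g2_candidates:
                if not p1_ok:
                    rejected["pressure_d1"] += 1
                    continue
                eta2 = _eta_max((g2_spec.phi_init, g2_spec.phi_final),
                                ranges.d2_strong_is_acn, ranges.temperature_d2)
                dp2 = pressure_drop(ranges.column_d2, f2, eta2)
                if dp2 > min(ranges.column_d2.max_pressure, limits.max_pressure_d2):
                    rejected["pressure_d2"] += 1
                    continue
                if (f1 + f_mu) * ts > loop * (1.0 + 1e-12):
                    rejected["loop"] += 1
                    continue
                if ts < g2_spec.t_grad + limits.reequilibration_time - 1e-12:
                    rejected["cycle"] += 1
                    continue
                g1 = GradientProgram(
                    g1_spec.phi_init, g1_spec.phi_final, g1_spec.t_grad,
                    flow=f1, dwell_volume=ranges.dwell_volume_d1,
                )
                g2 = GradientProgram(
                    g2_spec.phi_init, g2_spec.phi_final, g2_spec.t_grad,
                    flow=f2, dwell_volume=ranges.dwell_volume_d2,
                )
                configs.append(
                    ExperimentalConfig(
                        column_d1=ranges.column_d1,
                        gradient_d1=g1,
                        column_d2=ranges.column_d2,
                        gradient_d2=g2,
                        modulation=ModulationSettings(
                            sampling_time=ts, makeup_flow=f_mu, loop_volume=loop,
                            makeup_composition=ranges.makeup_composition,
                        ),
                        limits=limits,
                    )
                )
    if not configs:
        raise InfeasibleConfigError(
            "no feasible configuration; rejections: "
            + ", ".join(f"{k}={v}" for k, v in rejected.items())
        )
    return configs


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _k_at(model: RetentionModel, phi: float) -> float:
    return float(retention_factor(model, max(phi, _PHI_MIN) if model.kind == "adsorption" else phi))


def _first_dimension(config: ExperimentalConfig, analyte: Analyte) -> PerAnalyteDetail:
    """¹D retention, width and transfer-fraction bookkeeping for one analyte."""
    g1 = config.gradient_d1
    state1 = column_state(config.column_d1, analyte.vd_d1, g1.flow)
    res = predict_gradient_retention(analyte.model_d1, g1, state1.t0)
    if not res.eluted:
        warnings.warn(f"analyte {analyte.name} does not elute in the first dimension")
        return PerAnalyteDetail(name=analyte.name, eluted=False)
    k_e1 = local_k_at_elution(analyte.model_d1, g1, res.t_r, state1.t0)
    var1 = total_peak_variance(
        column_variance_gradient(state1, k_e1),
        0.0,
        config.limits.extra_column_variance_d1 / g1.flow**2,
    )
    ts = config.modulation.sampling_time
    frac = int(res.t_r / ts)
    phi1 = float(composition_at_inlet(g1, max(res.t_r - state1.t0, 0.0)))
    geom = modulation_geometry(
        g1.flow, config.modulation.makeup_flow, ts, config.modulation.loop_volume
    )
    phi_ss = sample_solvent_composition(
        phi1, g1.flow, config.modulation.makeup_flow, config.modulation.makeup_composition
    )
    return PerAnalyteDetail(
        name=analyte.name,
        eluted=True,
        t_r1=res.t_r,
        sigma1=math.sqrt(var1),
        fraction_index=frac,
        phi1=phi1,
        phi_ss=phi_ss,
        v_inj=geom.total_fraction_volume,
    )


def _assemble_metrics(
    config: ExperimentalConfig, details: list[PerAnalyteDetail]
) -> PerformanceMetrics:
    ok = [d for d in details if d.eluted]
    if not ok:
        raise InfeasibleConfigError("no analyte elutes under this configuration")
    g1, g2 = config.gradient_d1, config.gradient_d2
    ts = config.modulation.sampling_time
    t0_1 = config.column_d1.void_volume / g1.flow
    t0_2 = config.column_d2.void_volume / g2.flow

    sigma1 = float(np.mean([d.sigma1 for d in ok]))
    t_last1 = max(d.t_r1 for d in ok)
    n1c = dimension_peak_capacity((t0_1, t_last1), sigma1)
    beta = undersampling_factor(ts, sigma1)
    n1c_corr = max(n1c / beta, 1.0)

    sigma2 = float(np.mean([d.sigma2 for d in ok]))
    t_last2 = max(d.t_r2 for d in ok)
    n2c = dimension_peak_capacity((t0_2, min(ts, t_last2) if ts > t0_2 else t_last2), sigma2)

    nc2d = two_dimensional_peak_capacity(n1c_corr, max(n2c, 1.0))
    dil = dilution_factor(
        sigma_v_d1=[d.sigma1 * g1.flow for d in ok],
        v_inj_d1=config.limits.sample_volume_d1,
        sigma_v_d2=[d.sigma2 * g2.flow for d in ok],
        v_inj_d2=[d.v_inj for d in ok],
        f1=g1.flow,
        f_mu=config.modulation.makeup_flow,
    )
    return PerformanceMetrics(
        n1c_corrected=n1c_corr,
        n2c=max(n2c, 1.0),
        nc_2d=nc2d,
        analysis_time=t_last1,
        dilution_total=dil,
        n1c_raw=n1c,
        undersampling_beta=beta,
    )


def evaluate_config_theoretical(
    config: ExperimentalConfig, analytes: Sequence[Analyte]
) -> ParetoPoint:
    """Score a configuration using the theoretical injection equation.

    Per analyte, the second-dimension band variance is the sum of the
    column term, the injection term (Gaussian assumption) and the
    post-column extra-column term.
    """
    g2 = config.gradient_d2
    details: list[PerAnalyteDetail] = []
    for analyte in analytes:
        d = _first_dimension(config, analyte)
        if d.eluted:
            state2 = column_state(config.column_d2, analyte.vd_d2, g2.flow)
            res2 = predict_gradient_retention(analyte.model_d2, g2, state2.t0)
            if not res2.eluted:
                warnings.warn(
                    f"analyte {analyte.name} does not elute in the second dimension"
                )
                d = PerAnalyteDetail(name=analyte.name, eluted=False)
            else:
                k_e2 = local_k_at_elution(analyte.model_d2, g2, res2.t_r, state2.t0)
                k_ss = _k_at(analyte.model_d2, d.phi_ss)
                _, inj_var_t = injection_variance(
                    InjectionContext(v_inj=d.v_inj, flow=g2.flow, k_e=k_e2, k_ss=k_ss)
                )
                var2 = total_peak_variance(
                    column_variance_gradient(state2, k_e2),
                    inj_var_t,
                    config.limits.extra_column_variance_d2 / g2.flow**2,
                )
                d.t_r2 = res2.t_r
                d.sigma2 = math.sqrt(var2)
                d.k_e2 = k_e2
                d.k_ss = k_ss
        details.append(d)
    return ParetoPoint(config, _assemble_metrics(config, details), "theoretical", details)


def evaluate_config_simulated(
    config: ExperimentalConfig,
    analytes: Sequence[Analyte],
    n_max: int = 20_000,
    keep_profiles: bool = False,
    tail_constant: float | None = None,
) -> ParetoPoint:
    """Score a configuration using Craig-simulated ²D elution profiles.

    The second-dimension retention time is the simulated apex and the
    peak sigma the second-moment sigma (robust to distorted peaks); only
    the post-column extra-column variance is added on top, since column
    and injection broadening are intrinsic to the simulation.  Split-peak
    counts are recorded per analyte.
    """
    g2 = config.gradient_d2
    details: list[PerAnalyteDetail] = []
    for analyte in analytes:
        d = _first_dimension(config, analyte)
        if d.eluted:
            state2 = column_state(config.column_d2, analyte.vd_d2, g2.flow)
            n_plates = int(round(state2.n_plates))
            if n_plates > n_max:
                warnings.warn(
                    f"plate count {n_plates} capped at {n_max} for simulation"
                )
                n_plates = n_max
            fill = d.v_inj / config.modulation.loop_volume
            inj = make_injection_profile(
                loop_volume=config.modulation.loop_volume,
                fill_fraction=fill,
                flow=g2.flow,
                sample_solvent=d.phi_ss,
                mobile_phase_init=g2.phi_init,
                tail_constant=tail_constant,
            )
            profile = simulate_elution(
                analyte.model_d2,
                CraigColumn(n_plates=n_plates, t0=state2.t0),
                g2,
                inj,
                analyte=analyte.name,
            )
            if not profile.fully_eluted:
                d = PerAnalyteDetail(name=analyte.name, eluted=False)
            else:
                mom = profile_moments(profile)
                d.t_r2 = mom.t_apex
                d.sigma2 = math.sqrt(
                    mom.sigma_moment**2
                    + config.limits.extra_column_variance_d2 / g2.flow**2
                )
                d.k_e2 = local_k_at_elution(analyte.model_d2, g2, mom.t_apex, state2.t0)
                d.k_ss = _k_at(analyte.model_d2, d.phi_ss)
                d.n_maxima = mom.n_maxima
                if keep_profiles:
                    d.profile = profile
        details.append(d)
    return ParetoPoint(config, _assemble_metrics(config, details), "simulated", details)


# ---------------------------------------------------------------------------
# Pareto filtering and the hybrid algorithm
# ---------------------------------------------------------------------------


def pareto_front(points: Sequence[ParetoPoint]) -> list[ParetoPoint]:
    """Non-dominated subset under (max nc_2d, min time, min dilution).

    A point is dominated when another is at least as good in every
    objective and strictly better in one.  Points with identical
    objective vectors are all retained.  Output is sorted by
    (analysis time, -nc_2d) for stability.
    """
    if not points:
        raise ValueError("need at least one point")
    # sign-normalize so that larger is better in every column
    obj = np.array(
        [
            (p.metrics.nc_2d, -p.metrics.analysis_time, -p.metrics.dilution_total)
            for p in points
        ]
    )
    n = len(points)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        geq = np.all(obj >= obj[i], axis=1)
        gt = np.any(obj > obj[i], axis=1)
        if np.any(geq & gt):
            keep[i] = False
    front = [p for p, k in zip(points, keep) if k]
    front.sort(key=lambda p: (p.metrics.analysis_time, -p.metrics.nc_2d))
    return front


def hybrid_optimize(
    ranges: ParameterRanges,
    analytes: Sequence[Analyte],
    n_max: int = 20_000,
    keep_profiles: bool = False,
) -> HybridResult:
    """Two-stage optimization: theoretical front, then simulated refinement.

    Stage 1 evaluates every feasible configuration with the theoretical
    injection equation and keeps the Pareto front.  Stage 2 re-evaluates
    *only* the front configurations with the Craig simulator (one
    simulation per analyte per point).  Stage 3 re-applies Pareto
    filtering to the simulated points; points whose simulated performance
    is dominated are reported in ``removed``.
    """
    configs = enumerate_feasible_configs(ranges)
    theoretical: list[ParetoPoint] = []
    for cfg in configs:
        try:
            theoretical.append(evaluate_config_theoretical(cfg, analytes))
        except InfeasibleConfigError:
            continue
    if not theoretical:
        raise InfeasibleConfigError("no configuration could be evaluated")
    preliminary = pareto_front(theoretical)

    simulated = [
        evaluate_config_simulated(p.config, analytes, n_max=n_max, keep_profiles=keep_profiles)
        for p in preliminary
    ]
    n_ok = sum(1 for p in simulated for d in p.detail if d.eluted)
    refined = pareto_front(simulated)
    refined_ids = {id(p) for p in refined}
    removed = [p for p in simulated if id(p) not in refined_ids]
    return HybridResult(
        preliminary_front=preliminary,
        refined_front=refined,
        removed=removed,
        simulation_count=n_ok,
        n_configs=len(configs),
        n_feasible=len(theoretical),
    )


def front_to_dataframe(points: Sequence[ParetoPoint]):
    """Tabulate a front: one row per point with config fields and metrics."""
    import pandas as pd

    rows = []
    for p in points:
        c = p.config
        rows.append(
            {
                "flow_d1_ul_min": c.gradient_d1.flow,
                "flow_d2_ul_min": c.gradient_d2.flow,
                "sampling_time_min": c.modulation.sampling_time,
                "makeup_flow_ul_min": c.modulation.makeup_flow,
                "loop_volume_ul": c.modulation.loop_volume,
                "phi_init_d1": c.gradient_d1.phi_init,
                "phi_final_d1": c.gradient_d1.phi_final,
                "t_grad_d1_min": c.gradient_d1.t_grad,
                "phi_init_d2": c.gradient_d2.phi_init,
                "phi_final_d2": c.gradient_d2.phi_final,
                "t_grad_d2_min": c.gradient_d2.t_grad,
                "evaluation": p.evaluation,
                "n1c_corrected": p.metrics.n1c_corrected,
                "n2c": p.metrics.n2c,
                "nc_2d": p.metrics.nc_2d,
                "analysis_time_min": p.metrics.analysis_time,
                "dilution_total": p.metrics.dilution_total,
                "n_split_analytes": sum(1 for d in p.detail if d.n_maxima > 1),
            }
        )
    return pd.DataFrame(rows)


def config_from_row(ranges: ParameterRanges, row) -> ExperimentalConfig:
    """Rebuild a configuration from one front-CSV row plus fixed hardware."""
    g1 = GradientProgram(
        float(row["phi_init_d1"]), float(row["phi_final_d1"]), float(row["t_grad_d1_min"]),
        flow=float(row["flow_d1_ul_min"]), dwell_volume=ranges.dwell_volume_d1,
    )
    g2 = GradientProgram(
        float(row["phi_init_d2"]), float(row["phi_final_d2"]), float(row["t_grad_d2_min"]),
        flow=float(row["flow_d2_ul_min"]), dwell_volume=ranges.dwell_volume_d2,
    )
    return ExperimentalConfig(
        column_d1=ranges.column_d1,
        gradient_d1=g1,
        column_d2=ranges.column_d2,
        gradient_d2=g2,
        modulation=ModulationSettings(
            sampling_time=float(row["sampling_time_min"]),
            makeup_flow=float(row["makeup_flow_ul_min"]),
            loop_volume=float(row["loop_volume_ul"]),
            makeup_composition=ranges.makeup_composition,
        ),
        limits=ranges.limits,
    )


def full_simulation_optimize(
    ranges: ParameterRanges,
    analytes: Sequence[Analyte],
    n_max: int = 20_000,
    keep_profiles: bool = False,
) -> list[ParetoPoint]:
    """Simulation-only optimization over the whole grid (oracle route).

    Computationally heavy — intended for small grids, cross-checks and
    the removed-point analysis; the hybrid route exists precisely to
    avoid running this at scale.
    """
    configs = enumerate_feasible_configs(ranges)
    points: list[ParetoPoint] = []
    for cfg in configs:
        try:
            points.append(
                evaluate_config_simulated(cfg, analytes, n_max=n_max, keep_profiles=keep_profiles)
            )
        except InfeasibleConfigError:
            continue
    if not points:
        raise InfeasibleConfigError("no configuration could be evaluated")
    return pareto_front(points)
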