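"""Enumeration, config evaluation, Pareto filtering and the hybrid algorithm."""

import numpy as np
import pytest

import lcxlc as L
from lcxlc.metrics import InfeasibleConfigError, InstrumentLimits, PerformanceMetrics
from lcxlc.optimizer import ParetoPoint


def _dummy_point(nc2d, time, dil):
    metrics = PerformanceMetrics(
        n1c_corrected=1, n2c=1, nc_2d=nc2d, analysis_time=time, dilution_total=dil
    )
    return ParetoPoint(config=None, metrics=metrics, evaluation="theoretical")


def _brute_force_front(points):
    """O(n^2) dominance oracle: keep p unless some q is >= everywhere and > once."""
    out = []
    for p in points:
        a = (p.metrics.nc_2d, -p.metrics.analysis_time, -p.metrics.dilution_total)
        dominated = False
        for q in points:
            b = (q.metrics.nc_2d, -q.metrics.analysis_time, -q.metrics.dilution_total)
            if all(x >= y for x, y in zip(b, a)) and any(x > y for x, y in zip(b, a)):
                dominated = True
                break
        if not dominated:
            out.append(p)
    return out


class TestEnumeration:
    def test_cartesian_product_count(self, column_d1, column_d2):
        ranges = L.ParameterRanges(
            column_d1=column_d1, column_d2=column_d2,
            flows_d1=[17.0], flows_d2=[2000.0],
            sampling_times=[0.5, 1.0],
            makeup_flows=[50.0, 100.0],
            loop_volumes=[200.0, 300.0],
            gradients_d1=[L.GradientSpec(0.01, 0.25, 55.0)],
        )
        assert len(L.enumerate_feasible_configs(ranges)) == 8

    def test_loop_constraint_excludes(self, column_d1, column_d2):
        # 17 + 153 µL/min over 0.75 min = 127.5 µL: needs the larger loop
        ranges = L.ParameterRanges(
            column_d1=column_d1, column_d2=column_d2,
            flows_d1=[17.0], flows_d2=[2000.0],
            sampling_times=[0.75],
            makeup_flows=[153.0],
            loop_volumes=[80.0, 160.0],
            gradients_d1=[L.GradientSpec(0.01, 0.25, 55.0)],
        )
        configs = L.enumerate_feasible_configs(ranges)
        assert [c.modulation.loop_volume for c in configs] == [160.0]

    def test_pressure_cap_empty_error(self, column_d1, column_d2):
        ranges = L.ParameterRanges(
            column_d1=column_d1, column_d2=column_d2,
            flows_d1=[17.0], flows_d2=[2000.0],
            sampling_times=[0.75], makeup_flows=[68.0], loop_volumes=[80.0],
            gradients_d1=[L.GradientSpec(0.01, 0.25, 55.0)],
            limits=InstrumentLimits(max_pressure_d1=0.01),
        )
        with pytest.raises(InfeasibleConfigError, match="pressure_d1"):
            L.enumerate_feasible_configs(ranges)

    def test_cycle_constraint(self, column_d1, column_d2):
        # explicit ²D gradient longer than the sampling time is rejected
        ranges = L.ParameterRanges(
            column_d1=column_d1, column_d2=column_d2,
            flows_d1=[17.0], flows_d2=[2000.0],
            sampling_times=[0.65], makeup_flows=[68.0], loop_volumes=[80.0],
            gradients_d1=[L.GradientSpec(0.01, 0.25, 55.0)],
            gradients_d2=[L.GradientSpec(0.01, 0.55, 0.84)],
        )
        with pytest.raises(InfeasibleConfigError, match="cycle"):
            L.enumerate_feasible_configs(ranges)


class TestParetoFront:
    def test_single_point(self):
        p = _dummy_point(10, 1, 1)
        assert L.pareto_front([p]) == [p]

    def test_hand_built_dominance(self):
        pts = [
            _dummy_point(100, 10, 5),   # front
            _dummy_point(100, 12, 5),   # dominated (slower, same rest)
            _dummy_point(120, 15, 6),   # front (best capacity)
            _dummy_point(80, 8, 4),     # front (fastest / cleanest)
            _dummy_point(80, 9, 4.5),   # dominated
        ]
        front = L.pareto_front(pts)
        assert set(map(id, front)) == set(map(id, [pts[0], pts[2], pts[3]]))

    def test_matches_bruteforce_on_random_points(self):
        rng = np.random.default_rng(42)
        pts = [
            _dummy_point(nc, t, d)
            for nc, t, d in zip(
                rng.uniform(100, 3000, 500),
                rng.uniform(10, 60, 500),
                rng.uniform(1, 10, 500),
            )
        ]
        front = L.pareto_front(pts)
        oracle = _brute_force_front(pts)
        assert set(map(id, front)) == set(map(id, oracle))

    def test_duplicates_retained(self):
        a, b = _dummy_point(10, 1, 1), _dummy_point(10, 1, 1)
        assert len(L.pareto_front([a, b])) == 2

    def test_adding_dominated_point_is_noop(self):
        pts = [_dummy_point(100, 10, 5), _dummy_point(120, 15, 6)]
        front1 = L.pareto_front(pts)
        front2 = L.pareto_front(pts + [_dummy_point(90, 11, 6)])
        assert set(map(id, front1)) == set(map(id, front2))


def _gaussian_limit_setup(column_d1, column_d2):
    """Matched solvent, tiny full-loop injection, isocratic ²D at high k.

    Flat ²D composition equal to the blended sample solvent removes both
    mismatch and gradient compression; a flat plate-height curve pins the
    ²D plate count at 1000 so theory and simulation discretize the same
    column; k_e ~ 40-70 keeps the Craig and plate-theory variances equal
    to a few percent.  This is the regime where the two evaluation
    routes must agree.
    """
    phi2 = 0.01
    cfg = L.ExperimentalConfig(
        column_d1=column_d1,
        gradient_d1=L.GradientProgram(0.01, 0.25, 55.0, flow=17.0, dwell_volume=13.0),
        column_d2=column_d2,
        gradient_d2=L.GradientProgram(phi2, phi2, 0.5, flow=2000.0, dwell_volume=55.0),
        modulation=L.ModulationSettings(
            sampling_time=0.02, makeup_flow=283.0, loop_volume=6.0,  # full 6 µL loop
            makeup_composition=phi2,
        ),
    )
    flat_h = L.VanDeemterCurve(50, 0, 0)  # H = 50 µm -> N = 1000 on 50 mm
    analytes = [
        L.Analyte("hi_k_a", L.RetentionModel.adsorption(0.5, 1.2),
                  L.RetentionModel.lss(30, 5), flat_h, flat_h),
        L.Analyte("hi_k_b", L.RetentionModel.adsorption(0.9, 1.5),
                  L.RetentionModel.lss(45, 6), flat_h, flat_h),
    ]
    return cfg, analytes


class TestEvaluation:
    def test_makeup_flow_linearity(self, column_d1, column_d2, analytes3):
        base = dict(
            column_d1=column_d1,
            gradient_d1=L.GradientProgram(0.01, 0.25, 55.0, flow=17.0, dwell_volume=13.0),
            column_d2=column_d2,
            gradient_d2=L.GradientProgram(0.01, 0.55, 0.5, flow=2000.0, dwell_volume=55.0),
        )
        p_low = L.evaluate_config_theoretical(
            L.ExperimentalConfig(
                **base,
                modulation=L.ModulationSettings(sampling_time=0.75, makeup_flow=68.0,
                                                loop_volume=300.0),
            ),
            analytes3,
        )
        p_high = L.evaluate_config_theoretical(
            L.ExperimentalConfig(
                **base,
                modulation=L.ModulationSettings(sampling_time=0.75, makeup_flow=136.0,
                                                loop_volume=300.0),
            ),
            analytes3,
        )
        ratio = (17 + 136) / (17 + 68)
        v_low = [d.v_inj for d in p_low.detail if d.eluted]
        v_high = [d.v_inj for d in p_high.detail if d.eluted]
        assert np.allclose(np.array(v_high) / np.array(v_low), ratio)

    def test_simulated_matches_theory_for_matched_small_injection(
        self, column_d1, column_d2
    ):
        cfg, analytes = _gaussian_limit_setup(column_d1, column_d2)
        pt = L.evaluate_config_theoretical(cfg, analytes)
        ps = L.evaluate_config_simulated(cfg, analytes, tail_constant=0.0)
        for dt_, ds in zip(pt.detail, ps.detail):
            assert dt_.eluted and ds.eluted
            assert ds.t_r2 == pytest.approx(dt_.t_r2, rel=0.05)
            assert ds.sigma2 == pytest.approx(dt_.sigma2, rel=0.05)
        assert ps.metrics.n2c == pytest.approx(pt.metrics.n2c, rel=0.05)

    def test_overload_simulated_capacity_not_higher(self, column_d1, column_d2, analytes3):
        # strong sample solvent + big fraction: the simulator must not
        # predict a sharper separation than the Gaussian theory
        cfg = L.ExperimentalConfig(
            column_d1=column_d1,
            gradient_d1=L.GradientProgram(0.01, 0.25, 55.0, flow=17.0, dwell_volume=13.0),
            column_d2=column_d2,
            gradient_d2=L.GradientProgram(0.01, 0.01, 0.5, flow=2000.0, dwell_volume=55.0),
            modulation=L.ModulationSettings(
                sampling_time=1.1, makeup_flow=153.0, loop_volume=230.0,
                makeup_composition=0.9,  # deliberately strong diluent
            ),
        )
        pt = L.evaluate_config_theoretical(cfg, analytes3)
        ps = L.evaluate_config_simulated(cfg, analytes3, n_max=1500)
        assert ps.metrics.n2c <= pt.metrics.n2c


class TestHybrid:
    def test_simulation_budget_is_front_size(self, focused_ranges, analytes3):
        hy = L.hybrid_optimize(focused_ranges, analytes3, n_max=1200)
        assert hy.simulation_count == len(hy.preliminary_front) * len(analytes3)

    def test_refined_configs_subset_of_preliminary(self, focused_ranges, analytes3):
        hy = L.hybrid_optimize(focused_ranges, analytes3, n_max=1200)
        prelim_cfgs = {id(p.config) for p in hy.preliminary_front}
        assert all(id(p.config) in prelim_cfgs for p in hy.refined_front)

    def test_mismatch_grid_removes_points(self, mismatch_ranges, analytes3):
        """Solvent-mismatch grid: at least one theoretically optimal point is
        dropped once simulated (the overload-penalty phenomenon), and the
        dropped configurations are absent from the full-simulation front too."""
        hy = L.hybrid_optimize(mismatch_ranges, analytes3, n_max=1200)
        assert len(hy.removed) >= 1
        full = L.full_simulation_optimize(mismatch_ranges, analytes3, n_max=1200)
        full_cfgs = {id(p.config) for p in full}
        # removed points were re-simulated copies; compare by config identity
        assert all(id(p.config) not in full_cfgs for p in hy.removed)

    def test_deterministic(self, focused_ranges, analytes3):
        h1 = L.hybrid_optimize(focused_ranges, analytes3, n_max=800)
        h2 = L.hybrid_optimize(focused_ranges, analytes3, n_max=800)
        v1 = [p.metrics.objectives() for p in h1.refined_front]
        v2 = [p.metrics.objectives() for p in h2.refined_front]
        assert v1 == v2
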