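"""Craig simulator: binomial exactness, Gaussian limit, mass conservation,
injection-profile model, moments and split-peak analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, norm

import lcxlc as L


def _pulse_injection(v=0.5, flow=2000.0, phi=0.3):
    """Near-delta matched-solvent injection for limit tests."""
    return L.make_injection_profile(
        loop_volume=v, fill_fraction=1.0, flow=flow,
        sample_solvent=phi, mobile_phase_init=phi, tail_constant=0.0,
    )


def _flat_gradient(phi=0.3, flow=2000.0):
    return L.GradientProgram(phi, phi, 1.0, flow=flow)


class TestInjectionProfileModel:
    def test_rectangular_limit(self):
        prof = L.make_injection_profile(80, 1.0, 2000, 0.5, 0.0, tail_constant=0.0)
        assert prof.duration == pytest.approx(80 / 2000, rel=1e-6)
        inside = prof.concentration > 0
        assert np.allclose(prof.concentration[inside], prof.concentration[inside][0])
        assert np.all(prof.phi[inside] == 0.5)

    def test_partial_fill_mobile_phase_first(self):
        # fill=0.5, loop=80 µL, 2000 µL/min: 0.02 min of mobile phase then 0.02 min plug
        prof = L.make_injection_profile(80, 0.5, 2000, 0.7, 0.05, tail_constant=0.0)
        t_first_analyte = prof.time[prof.concentration > 0][0]
        assert t_first_analyte == pytest.approx(0.02, abs=2e-4)
        width = prof.time[prof.concentration > 0][-1] - t_first_analyte
        assert width == pytest.approx(0.02, abs=2e-4)
        assert np.all(prof.phi[prof.concentration == 0][:10] == pytest.approx(0.05))

    @given(
        loop=st.floats(20, 260),
        fill=st.floats(0.05, 1.0),
        flow=st.floats(500, 3000),
        tail=st.floats(0.0, 0.3),
    )
    @settings(max_examples=30, deadline=None)
    def test_mass_always_one(self, loop, fill, flow, tail):
        prof = L.make_injection_profile(loop, fill, flow, 0.5, 0.0,
                                        tail_constant=tail * loop)
        assert np.sum(prof.concentration) * prof.dt == pytest.approx(1.0, abs=1e-9)

    def test_overfill_rejected(self):
        with pytest.raises(ValueError):
            L.make_injection_profile(80, 1.2, 2000, 0.5, 0.0)


class TestBinomialOracle:
    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("n_steps", [1, 7, 60, 200])
    def test_cell_occupancy_is_binomial(self, k, n_steps):
        """After n steps a unit pulse occupies cell r with probability
        C(n-1, r) p^r q^(n-1-r), p = 1/(1+k)."""
        n_cells = 200
        dist = L.craig_cell_distribution(k, n_cells, n_steps)
        expected = binom.pmf(np.arange(n_cells), n_steps - 1, 1.0 / (1.0 + k))
        assert np.abs(dist - expected).max() < 1e-9

    @pytest.mark.parametrize("n_steps", [1, 33, 150])
    def test_stepwise_mass_conservation(self, n_steps):
        dist = L.craig_cell_distribution(2.0, 400, n_steps)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestGaussianLimit:
    def test_apex_mean_and_plate_recovery(self):
        n, k, t0 = 1000, 50.0, 0.1
        prof = L.simulate_elution(
            L.RetentionModel.lss(k, 0.0),
            L.CraigColumn(n_plates=n, t0=t0),
            _flat_gradient(),
            _pulse_injection(),
            horizon=2 * t0 * (1 + k),
        )
        assert prof.fully_eluted
        mom = L.profile_moments(prof)
        t_expected = t0 * (1 + k)
        assert mom.t_apex == pytest.approx(t_expected, rel=0.05)
        assert mom.t_mean == pytest.approx(t_expected, rel=0.05)
        n_recovered = (mom.t_apex / mom.sigma_moment) ** 2
        assert n_recovered == pytest.approx(n, rel=0.05)
        assert mom.n_maxima == 1

    def test_mass_conserved_under_gradient_mismatch(self):
        g = L.GradientProgram(0.01, 0.55, 0.46, flow=2000, dwell_volume=55)
        inj = L.make_injection_profile(80, 0.9, 2000, 0.7, 0.01)
        prof = L.simulate_elution(
            L.RetentionModel.lss(30, 15), L.CraigColumn(n_plates=1500, t0=0.106), g, inj
        )
        assert prof.fully_eluted
        assert prof.mass == pytest.approx(1.0, rel=1e-6)

    def test_deterministic(self):
        g = L.GradientProgram(0.01, 0.55, 0.46, flow=2000)
        inj = L.make_injection_profile(80, 0.6, 2000, 0.4, 0.01)
        col = L.CraigColumn(n_plates=500, t0=0.1)
        model = L.RetentionModel.lss(30, 15)
        p1 = L.simulate_elution(model, col, g, inj)
        p2 = L.simulate_elution(model, col, g, inj)
        assert np.array_equal(p1.flux, p2.flux)


class TestSolventEffects:
    def _simulate(self, sample_solvent, fill=0.9, n=1200):
        g = L.GradientProgram(0.01, 0.55, 0.46, flow=2000, dwell_volume=55)
        inj = L.make_injection_profile(80, fill, 2000, sample_solvent, 0.01)
        return L.simulate_elution(
            L.RetentionModel.lss(30, 15), L.CraigColumn(n_plates=n, t0=0.106), g, inj
        )

    def test_weak_sample_solvent_focuses(self):
        sig_weak = L.profile_moments(self._simulate(0.0)).sigma_moment
        sig_matched = L.profile_moments(self._simulate(0.01)).sigma_moment
        assert sig_weak < sig_matched

    def test_strong_solvent_overload_splits_peak(self):
        mom = L.profile_moments(self._simulate(0.7, fill=0.9))
        assert mom.n_maxima >= 2

    def test_sigma_monotone_in_fill(self):
        sigmas = [
            L.profile_moments(self._simulate(0.35, fill=f)).sigma_moment
            for f in (0.2, 0.5, 0.9)
        ]
        assert sigmas[0] <= sigmas[1] <= sigmas[2]


class TestProfileMoments:
    def _profile_from(self, t, y):
        return L.ElutionProfile(time=t, flux=y, n_plates=1000, dt=float(t[1] - t[0]))

    def test_gaussian_identity(self):
        t = np.arange(1, 20000) * 1e-4
        y = norm.pdf(t, 1.0, 0.01)
        mom = L.profile_moments(self._profile_from(t, y))
        assert mom.sigma_moment == pytest.approx(0.01, rel=1e-3)
        assert mom.sigma_halfheight == pytest.approx(0.01, rel=1e-3)
        assert mom.t_apex == pytest.approx(1.0, abs=1e-4)

    def test_rectangular_pulse_variance(self):
        t = np.arange(1, 10000) * 1e-4
        w = 0.2
        y = ((t > 0.4) & (t <= 0.4 + w)).astype(float)
        mom = L.profile_moments(self._profile_from(t, y))
        assert mom.sigma_moment == pytest.approx(w / math.sqrt(12), rel=1e-2)

    def test_bimodal_reports_global_apex_width(self):
        t = np.arange(1, 30000) * 1e-4
        y = norm.pdf(t, 1.0, 0.02) + 0.6 * norm.pdf(t, 2.0, 0.02)
        mom = L.profile_moments(self._profile_from(t, y))
        assert mom.n_maxima == 2
        assert mom.t_apex == pytest.approx(1.0, abs=1e-3)
        assert mom.sigma_halfheight == pytest.approx(0.02, rel=0.01)
        assert mom.sigma_moment > 0.3  # second moment sees both modes

    def test_zero_profile_rejected(self):
        t = np.arange(1, 100) * 1e-3
        with pytest.raises(ValueError):
            L.profile_moments(self._profile_from(t, np.zeros_like(t)))


class TestSplitDetection:
    def _profile_from(self, t, y):
        return L.ElutionProfile(time=t, flux=y, n_plates=1000, dt=float(t[1] - t[0]))

    def test_single_gaussian(self):
        t = np.arange(1, 10000) * 1e-4
        prof = self._profile_from(t, norm.pdf(t, 0.5, 0.02))
        assert L.detect_peak_splitting(prof) == 1

    def test_two_separated_gaussians(self):
        t = np.arange(1, 10000) * 1e-4
        y = norm.pdf(t, 0.3, 0.01) + norm.pdf(t, 0.7, 0.01)
        assert L.detect_peak_splitting(self._profile_from(t, y)) == 2

    def test_shoulder_below_prominence_ignored(self):
        t = np.arange(1, 10000) * 1e-4
        y = norm.pdf(t, 0.5, 0.05) + 0.002 * norm.pdf(t, 0.62, 0.005)
        assert L.detect_peak_splitting(self._profile_from(t, y), prominence=0.05) == 1

    def test_shallow_valley_merged(self):
        # two maxima whose valley stays above 80% of the lower peak: one peak
        t = np.arange(1, 10000) * 1e-4
        y = norm.pdf(t, 0.48, 0.05) + norm.pdf(t, 0.56, 0.05)
        assert L.detect_peak_splitting(self._profile_from(t, y)) == 1
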