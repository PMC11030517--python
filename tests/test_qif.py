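"""Single-unit, pair, and driven-pair QIF dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frustranet as fn
from frustranet.qif import IntegratorConfig, _integrate_reset_system


class TestPeriodFormula:
    def test_b_one_gives_quarter_pi(self):
        assert fn.qif_period(1.0) == pytest.approx(math.pi / 4, rel=1e-12)

    def test_strictly_decreasing_in_b(self):
        bs = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        taus = fn.qif_period(bs)
        assert np.all(np.diff(taus) < 0)

    def test_matches_numerical_transit_integral(self):
        # independent oracle: tau = integral_0^1 dv / (b + v^2) by quadrature
        from scipy.integrate import quad

        for b in (0.01, 0.5, 1.0, 10.0):
            tau_quad, _ = quad(lambda v: 1.0 / (b + v * v), 0.0, 1.0)
            assert fn.qif_period(b) == pytest.approx(tau_quad, rel=1e-9)

    def test_rejects_non_positive_b(self):
        with pytest.raises(ValueError):
            fn.qif_period(0.0)
        with pytest.raises(ValueError):
            fn.qif_period(-1.0)

    def test_inverse_known_values(self):
        assert fn.b_from_period(math.pi / 4) == pytest.approx(1.0, rel=1e-10)
        # frozen value from an independent bisection on the forward formula
        assert fn.b_from_period(20.0) == pytest.approx(0.005596004599808, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=1000.0))
    def test_inverse_round_trip(self, tau):
        assert fn.qif_period(fn.b_from_period(tau)) == pytest.approx(tau, rel=1e-10)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "b,v_reset,expected",
        [
            (0.01, 0.0, fn.Regime.TONIC_SPIKING),
            (1.0, 0.0, fn.Regime.TONIC_SPIKING),
            (-1.0, -2.0, fn.Regime.EXCITABLE),
            (-1.0, 0.5, fn.Regime.EXCITABLE),
            (-4.0, 2.5, fn.Regime.RESET_ABOVE_SADDLE_SPIKING),
            (0.0, 0.0, fn.Regime.ON_BIFURCATION),
            (0.0, -1.0, fn.Regime.ON_BIFURCATION),
            (-1.0, 1.0, fn.Regime.ON_BIFURCATION),  # reset exactly on the saddle
        ],
    )
    def test_regions_of_the_bifurcation_plane(self, b, v_reset, expected):
        assert fn.classify_regime(b, v_reset, v_peak=3.0) == expected


class TestSingleUnitIntegration:
    def test_interspike_interval_matches_analytic_period(self):
        tau = math.pi / 4
        _, spikes = fn.integrate_qif(
            fn.NeuronParams(b=1.0), 0.0, 10 * tau, IntegratorConfig(dt=tau / 1000)
        )
        isi = spikes.intervals()
        assert isi.size >= 8
        assert abs(isi.mean() - tau) / tau < 0.005

    def test_period_error_shrinks_with_dt(self):
        # Euler halves its period error as dt halves (first order); RK4 is
        # already at rounding level at dt = tau/1000.
        tau = math.pi / 4
        errs = []
        for div in (200, 400, 800):
            _, spikes = fn.integrate_qif(
                fn.NeuronParams(b=1.0), 0.0, 10 * tau,
                IntegratorConfig(dt=tau / div, method="euler"),
            )
            errs.append(abs(spikes.intervals().mean() - tau))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < errs[0] / 3  # at least first-order decay
        _, spikes = fn.integrate_qif(
            fn.NeuronParams(b=1.0), 0.0, 10 * tau, IntegratorConfig(dt=tau / 1000)
        )
        assert abs(spikes.intervals().mean() - tau) < 1e-9

    def test_excitable_unit_relaxes_to_rest_without_spiking(self):
        # b = -1: stable rest at -1, saddle at +1; start at reset -2
        trace, spikes = fn.integrate_qif(
            fn.NeuronParams(b=-1.0, v_reset=-2.0, v_peak=1.0),
            -2.0,
            20.0,
            IntegratorConfig(dt=0.002),
        )
        assert len(spikes) == 0
        assert trace.values[-1] == pytest.approx(-1.0, abs=1e-3)
        assert np.all(np.diff(trace.values) >= 0)  # monotone approach

    def test_determinism(self):
        args = (fn.NeuronParams(b=1.0), 0.3, 5.0, IntegratorConfig(dt=0.001))
        t1, s1 = fn.integrate_qif(*args)
        t2, s2 = fn.integrate_qif(*args)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(s1.times, s2.times)

    def test_too_coarse_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            fn.integrate_qif(
                fn.NeuronParams(b=1.0), 0.0, 5.0, IntegratorConfig(dt=0.1)
            )


class TestCoupledPair:
    def test_zero_coupling_identical_initials_stay_identical(self):
        b = fn.b_from_period(20.0)
        (t1, t2), _ = fn.integrate_pair(
            fn.PairParams(b1=b, b2=b, g=0.0), [0.4, 0.4], 100.0
        )
        assert np.array_equal(t1.values, t2.values)

    @pytest.mark.parametrize("gT,bound,side", [(3.0, 0.05, "below"), (1 / 3, 0.4, "above")])
    def test_strong_coupling_in_phase_weak_anti_phase(self, gT, bound, side):
        """Strong diffusive coupling locks the pair in phase; weak coupling
        near the SNHO point drives it toward anti-phase."""
        from frustranet.metrics import spike_phase_offset

        tau = 20.0
        b = fn.b_from_period(tau)
        rng = np.random.default_rng(42)
        for _ in range(3):
            v0 = rng.random(2)
            _, (sa, sb) = fn.integrate_pair(
                fn.PairParams(b1=b, b2=b, g=gT / tau),
                v0,
                60 * tau,
                IntegratorConfig(dt=tau / 1000),
            )
            off = spike_phase_offset(sa, sb, tau) / tau
            if side == "below":
                assert off < bound
            else:
                assert off > bound


class TestDrivenPair:
    def test_reduces_to_single_unit_when_uncoupled(self):
        # g0 = 0, g = 0, b1 = 1: v1 spikes with period pi/4
        tau = math.pi / 4
        drive = fn.DriveParams.from_period(5.0, g0=0.0)
        (_, _, _), (su, s1, s2) = fn.integrate_driven_pair(
            fn.PairParams(b1=1.0, b2=1.0, g=0.0),
            drive,
            [0.0, 0.5],
            t_end=20.0,
            cfg=IntegratorConfig(dt=tau / 1000),
        )
        assert s1.intervals().mean() == pytest.approx(tau, rel=0.005)
        # drive spikes with its own period
        assert su.intervals().mean() == pytest.approx(5.0, rel=0.005)

    def test_symmetric_neurons_stay_identical(self):
        b0 = fn.b_from_period(20.0)
        drive = fn.DriveParams(b0=b0, g0=0.1)
        (tu, t1, t2), _ = fn.integrate_driven_pair(
            fn.PairParams(b1=b0, b2=b0, g=0.0), drive, [0.25, 0.25], t_end=80.0
        )
        assert np.array_equal(t1.values, t2.values)

    def test_drive_not_influenced_by_neurons(self):
        drive = fn.DriveParams.from_period(20.0, g0=0.3)
        cfg = IntegratorConfig(dt=0.01)
        (tu_a, *_), _ = fn.integrate_driven_pair(
            fn.PairParams(b1=0.01, b2=0.02, g=0.1), drive, [0.1, 0.9],
            t_end=60.0, cfg=cfg,
        )
        (tu_b, *_), _ = fn.integrate_driven_pair(
            fn.PairParams(b1=0.02, b2=0.03, g=0.0), drive, [0.7, 0.2],
            t_end=60.0, cfg=cfg,
        )
        assert np.array_equal(tu_a.values, tu_b.values)


class TestResetMechanics:
    def test_crossing_time_interpolated_within_step(self):
        # linear system dv/dt = 1 crosses v_peak = 1 from 0 exactly at t = 1
        times, trace, spikes = _integrate_reset_system(
            lambda t, y: np.ones_like(y),
            np.array([0.0]),
            2.0,
            0.3,  # grid does not align with the crossing
            np.array([0.0]),
            np.array([1.0]),
        )
        assert spikes[0][0] == pytest.approx(1.0, abs=1e-12)

    def test_trace_stays_within_reset_peak_band(self):
        _, trace, _ = _integrate_reset_system(
            lambda t, y: 1.0 + y * y,
            np.array([0.0]),
            10.0,
            0.001,
            np.array([0.0]),
            np.array([1.0]),
        )
        assert trace.min() >= 0.0
        assert trace.max() <= 1.0 + 1e-9
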