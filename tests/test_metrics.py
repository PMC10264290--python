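import numpy as np
import pytest

from dissectflow.inlet import MovingPlaneSeries, PlaneVelocityField
from dissectflow.metrics import (
    LuminalPlanePair,
    ViscosityModel,
    WSSHistory,
    bland_altman,
    cycle_rf,
    decompose,
    ecap_exceeds_threshold,
    flef,
    plane_flow,
    reynolds_check,
    rf_ratio,
    tawss_osi_ecap,
    tmp,
    velocity_errors,
    viscosity,
)
from dissectflow.synth import SynthSpec, gen_plane_series


def field_from_vz(vz, area=1.0):
    vz = np.asarray(vz, dtype=float)
    n = vz.size
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-5, 5, (n, 2)), np.zeros(n)])
    return PlaneVelocityField(
        points=pts,
        velocities=np.column_stack([np.zeros(n), np.zeros(n), vz]),
        area_weights=np.full(n, area),
        normal=np.array([0.0, 0.0, 1.0]),
    )


class TestFlowDecomposition:
    def test_symmetric_half_and_half(self):
        f = field_from_vz([1.0] * 5 + [-1.0] * 5)
        q_f, q_r = decompose(f)
        assert plane_flow(f) == pytest.approx(0.0, abs=1e-12)
        assert q_f == pytest.approx(5.0)
        assert q_r == pytest.approx(5.0)
        assert rf_ratio(q_f, q_r) == pytest.approx(1.0)

    def test_all_forward(self):
        f = field_from_vz([0.3, 0.7, 1.1])
        _, q_r = decompose(f)
        assert q_r == 0.0

    def test_zero_projection_contributes_to_neither(self):
        f = field_from_vz([1.0, 0.0, -1.0])
        q_f, q_r = decompose(f)
        assert (q_f, q_r) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_against_brute_force_partition(self):
        """Randomized field vs an explicit per-sample partition oracle."""
        rng = np.random.default_rng(42)
        vz = rng.normal(size=500)
        areas = rng.uniform(0.1, 2.0, size=500)
        f = field_from_vz(vz)
        f.area_weights = areas
        q_f, q_r = decompose(f)
        qf_o = sum(v * a for v, a in zip(vz, areas) if v > 0)
        qr_o = sum(-v * a for v, a in zip(vz, areas) if v < 0)
        assert q_f == pytest.approx(qf_o, abs=1e-12)
        assert q_r == pytest.approx(qr_o, abs=1e-12)
        assert plane_flow(f) == pytest.approx(q_f - q_r, abs=1e-10)


class TestCycleRF:
    def _series(self, vz_by_frame, T=1.0):
        nf = len(vz_by_frame)
        frames = [
            field_from_vz(vz_by_frame[j]) for j in range(nf)
        ]
        for j, f in enumerate(frames):
            f.timestamp = j * T / nf
        return MovingPlaneSeries(frames=frames, period=T)

    def test_constant_ratio(self):
        """Q_R/Q_F constant at 0.2 integrates to exactly 0.2."""
        series = self._series([[1.0] * 5 + [-0.2] * 5] * 4)
        assert cycle_rf(series) == pytest.approx(0.2, abs=1e-12)

    def test_no_reverse_flow_gives_zero(self):
        series = self._series([[0.5, 1.0, 0.2]] * 3)
        assert cycle_rf(series) == 0.0
        assert flef(series) == 0.0

    def test_prescribed_retrograde_fraction(self):
        """Generator with reverse/forward flow ratio 0.05 yields FLEF 5%."""
        spec = SynthSpec(
            seed=9, reverse_fraction=0.2, forward_speed=0.8,
            reverse_speed=0.05 * 0.8 * (1 - 0.2) / 0.2, n_points=400,
        )
        series, truth = gen_plane_series(spec, apply_motion=False)
        assert flef(series) == pytest.approx(5.0, rel=1e-9)
        assert flef(series) > 0.0  # reverse-flow instants exist

    def test_zero_forward_policy(self):
        series = self._series([[1.0, -0.5], [-1.0, -0.5], [1.0, -0.5]])
        with pytest.raises(ZeroDivisionError):
            cycle_rf(series, zero_forward="strict")
        with pytest.warns(UserWarning, match="zero forward"):
            val = cycle_rf(series)
        assert val >= 0.0


class TestTransmuralPressure:
    def _pair(self, diff, T=1.0):
        t = T * np.arange(len(diff)) / len(diff)
        base = np.full(len(diff), 80.0)
        return LuminalPlanePair(
            times=t, p_tl=base + np.asarray(diff), p_fl=base, period=T
        )

    def test_constant_offset(self):
        mean, peak = tmp(self._pair([2.0] * 8))
        assert (mean, peak) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_pure_sinusoid(self):
        t = np.arange(128) / 128
        mean, peak = tmp(self._pair(np.sin(2 * np.pi * t)))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert abs(peak) == pytest.approx(1.0)
        # earliest extremum of largest magnitude wins: +1 at t = T/4
        assert peak == pytest.approx(1.0)

    def test_piecewise_known_integral(self):
        # diff = t on [0, 1): closed-form cycle mean 0.5 with periodic closure
        t = np.arange(256) / 256
        pair = self._pair(t.copy())
        mean, _ = tmp(pair)
        # trapezoid with wrap adds the closing (1 -> 0) segment
        closed = np.trapezoid(np.append(t, t[0]), np.append(t, 1.0))
        assert mean == pytest.approx(closed, abs=1e-12)

    def test_antisymmetry(self):
        t = np.arange(64) / 64
        diff = 1.5 + 0.7 * np.sin(2 * np.pi * t)
        pair = self._pair(diff)
        swapped = LuminalPlanePair(
            times=pair.times, p_tl=pair.p_fl, p_fl=pair.p_tl, period=pair.period
        )
        m1, p1 = tmp(pair)
        m2, p2 = tmp(swapped)
        assert m2 == pytest.approx(-m1, abs=1e-12)
        assert p2 == pytest.approx(-p1, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LuminalPlanePair(
                times=np.arange(4) / 4.0, p_tl=np.zeros(4), p_fl=np.zeros(3),
                period=1.0,
            )


class TestWallShearIndices:
    def _history(self, tau, T=1.0):
        n_t = tau.shape[1]
        return WSSHistory(
            node_ids=np.arange(tau.shape[0]),
            times=T * np.arange(n_t) / n_t,
            tau=tau,
        )

    def test_constant_vector(self):
        tau = np.tile([2.0, 0.0, 0.0], (1, 64, 1))
        out = tawss_osi_ecap(self._history(tau))
        assert out["TAWSS_Pa"][0] == pytest.approx(2.0)
        assert out["OSI"][0] == 0.0
        assert out["ECAP_per_Pa"][0] == 0.0

    def test_reversing_sinusoid_analytic(self):
        """Fully reversing sinusoid: OSI = 0.5, TAWSS = (2/pi) tau0."""
        tau0 = 3.0
        t = np.arange(128) / 128
        tau = np.zeros((1, 128, 3))
        tau[0, :, 0] = tau0 * np.sin(2 * np.pi * t)
        out = tawss_osi_ecap(self._history(tau))
        assert out["OSI"][0] == pytest.approx(0.5, abs=1e-9)
        assert out["TAWSS_Pa"][0] == pytest.approx(2 * tau0 / np.pi, rel=1e-3)

    def test_ecap_is_osi_over_tawss(self):
        rng = np.random.default_rng(1)
        tau = rng.normal(size=(5, 40, 3))
        out = tawss_osi_ecap(self._history(tau))
        np.testing.assert_allclose(
            out["ECAP_per_Pa"], out["OSI"] / out["TAWSS_Pa"], rtol=1e-12
        )
        assert np.all((out["OSI"] >= 0) & (out["OSI"] <= 0.5))
        assert np.all(out["TAWSS_Pa"] >= 0)

    def test_zero_shear_node_flagged(self):
        tau = np.zeros((1, 16, 3))
        out = tawss_osi_ecap(self._history(tau))
        assert bool(out["degenerate"][0])
        assert out["OSI"][0] == 0.0 and out["ECAP_per_Pa"][0] == 0.0

    def test_threshold_helper(self):
        tau = np.zeros((2, 64, 3))
        t = np.arange(64) / 64
        tau[0, :, 0] = 0.2 * np.sin(2 * np.pi * t)  # ECAP = 0.5/(0.4/pi) = 3.93
        tau[1, :, 0] = 2.0
        out = tawss_osi_ecap(self._history(tau))
        hot = ecap_exceeds_threshold(out)
        assert list(hot["node_id"]) == [0]

    def test_sampling_rate_robustness(self):
        """Indices at 5 ms sampling differ from 1 ms sampling by < 1% on a
        smooth history."""
        T = 60.0 / 94.0
        rng = np.random.default_rng(3)
        outs = []
        for dt in (0.005, 0.001):
            n_t = int(round(T / dt))
            t = dt * np.arange(n_t)
            tau = np.zeros((4, n_t, 3))
            for i in range(4):
                m, o = 0.5 + i * 0.3, 1.0 + 0.2 * i
                tau[i, :, 0] = m + o * np.sin(2 * np.pi * t / T)
                tau[i, :, 1] = 0.4 * np.cos(2 * np.pi * t / T)
            outs.append(tawss_osi_ecap(WSSHistory(np.arange(4), t, tau)))
        for col in ("TAWSS_Pa", "OSI"):
            np.testing.assert_allclose(
                outs[0][col], outs[1][col], rtol=0.01, atol=1e-4
            )

    def test_dense_riemann_oracle(self):
        """Trapezoid-with-closure integrals match a dense Riemann-sum
        oracle on a smooth synthetic signal."""
        T = 1.0
        n_t = 2000
        t = T * np.arange(n_t) / n_t
        tau = np.zeros((1, n_t, 3))
        tau[0, :, 0] = 1.0 + 0.8 * np.sin(2 * np.pi * t)
        tau[0, :, 1] = 0.5 * np.cos(4 * np.pi * t)
        out = tawss_osi_ecap(self._history(tau, T=T))
        mag = np.linalg.norm(tau[0], axis=1)
        tawss_o = mag.mean()  # Riemann on the periodic grid
        vec_o = np.linalg.norm(tau[0].mean(axis=0))
        osi_o = 0.5 * (1 - vec_o / tawss_o)
        assert out["TAWSS_Pa"][0] == pytest.approx(tawss_o, abs=1e-6)
        assert out["OSI"][0] == pytest.approx(osi_o, abs=1e-6)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            WSSHistory(np.arange(1), np.array([0.0, 0.1, 0.35]), np.zeros((1, 3, 3)))


class TestViscosity:
    def test_limits(self):
        m = ViscosityModel()
        assert viscosity(0.0, m) == pytest.approx(m.mu0)
        assert viscosity(1e9, m) == pytest.approx(m.mu_inf, rel=1e-3)

    def test_closed_form(self):
        m = ViscosityModel()
        g = 37.5
        expected = m.mu_inf + (m.mu0 - m.mu_inf) * (
            1 + (m.lambda_s * g) ** m.a
        ) ** ((m.n - 1) / m.a)
        assert viscosity(g, m) == pytest.approx(expected, abs=1e-12)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            viscosity(-1.0, ViscosityModel())

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ViscosityModel(mu0=0.001, mu_inf=0.0035)


class TestReynolds:
    def test_constant_viscosity_arithmetic(self):
        """Re_p = rho V D / mu = 1056*1*0.03/0.0035 for constant 3.5 mPa s."""
        m = ViscosityModel(mu0=0.0035 * (1 + 1e-9), mu_inf=0.0035)
        rep = reynolds_check(1.0, 0.03, 94.0, m)
        assert rep.reynolds_peak == pytest.approx(1056 * 1 * 0.03 / 0.0035, rel=1e-6)

    def test_turbulent_flag_with_supplied_critical(self):
        m = ViscosityModel(mu0=0.0035 * (1 + 1e-9), mu_inf=0.0035)
        rep = reynolds_check(1.35, 0.03, 94.0, m, critical_reynolds=6959.0)
        assert rep.reynolds_critical == 6959.0
        assert rep.reynolds_peak > rep.reynolds_critical
        assert rep.turbulent

    def test_laminar_flag(self):
        m = ViscosityModel()
        rep = reynolds_check(0.1, 0.02, 60.0, m, critical_reynolds=5000.0)
        assert rep.reynolds_peak < 5000.0
        assert not rep.turbulent

    def test_womersley_positive_and_scaling(self):
        m = ViscosityModel(mu0=0.0035 * (1 + 1e-9), mu_inf=0.0035)
        r1 = reynolds_check(1.0, 0.03, 94.0, m)
        r2 = reynolds_check(1.0, 0.06, 94.0, m)
        assert r2.womersley == pytest.approx(2 * r1.womersley, rel=1e-6)


class TestBlandAltman:
    def test_identical_arrays(self):
        bias, lo, hi, pairs = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)
        assert np.all(pairs["difference"] == 0)

    def test_hand_computed_limits(self):
        bias, lo, hi, _ = bland_altman([1.0, 3.0], [2.0, 2.0])
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert lo == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 5.0])
        bias, lo, hi, _ = bland_altman(a + 0.7, a)
        assert bias == pytest.approx(0.7)
        assert lo == pytest.approx(hi) == pytest.approx(0.7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0, 2.0])


class TestVelocityErrors:
    def test_identical_fields(self):
        v = np.array([0.2, 0.5, 1.0])
        assert velocity_errors(v, v, 0.5) == (0.0, 0.0)

    def test_uniform_offset(self):
        vm = np.full(10, 1.1)
        vd = np.full(10, 1.0)
        peak, mean = velocity_errors(vm, vd, 0.5)
        assert peak == pytest.approx(20.0)
        assert mean == pytest.approx(20.0)

    def test_degenerate_zero_model(self):
        peak, mean = velocity_errors(np.zeros(4), np.ones(4), 1.0)
        assert peak == pytest.approx(-100.0)
        assert mean == pytest.approx(-100.0)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            velocity_errors(np.ones(3), np.ones(3), 0.0)
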