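"""Core ODE machinery: response function, explicit solutions, quadrature."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tftarget.ode import (
    FunctionOnGrid,
    KineticParams,
    ProteinParams,
    ResponseWeights,
    response_G,
    solve_transcription,
    solve_translation,
)


class TestResponseG:
    def test_neutral_point_is_half(self):
        rw = ResponseWeights(w=np.zeros(3), w0=0.0)
        assert response_G(np.ones(3), rw) == pytest.approx(0.5)

    def test_large_negative_bias_drives_to_zero(self):
        rw = ResponseWeights(w=np.array([1.0, -2.0, 0.3]), w0=-500.0)
        assert response_G(np.ones(3), rw) < 1e-12

    def test_direct_evaluation(self):
        # p=(e,1), w=(1,0), w0=0 -> sigmoid(1)
        rw = ResponseWeights(w=np.array([1.0, 0.0]), w0=0.0)
        val = response_G(np.array([np.e, 1.0]), rw)
        assert val == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_output_strictly_inside_unit_interval(self, rng):
        for _ in range(50):
            rw = ResponseWeights(w=rng.normal(0, 2, 4), w0=rng.normal())
            g = response_G(rng.lognormal(0, 1, 4), rw)
            assert 0.0 < g < 1.0

    def test_monotone_in_activity_sign_of_weight(self, rng):
        p_grid = np.linspace(0.1, 5.0, 30)
        for w_i, increasing in [(1.3, True), (-0.7, False)]:
            rw = ResponseWeights(w=np.array([w_i, 0.5]), w0=0.2)
            vals = [response_G(np.array([p, 1.7]), rw) for p in p_grid]
            diffs = np.diff(vals)
            assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_rejects_non_finite(self):
        rw = ResponseWeights(w=np.array([1.0]), w0=0.0)
        with pytest.raises(ValueError):
            response_G(np.array([np.nan]), rw)

    def test_positivity_floor_applied(self):
        rw = ResponseWeights(w=np.array([1.0]), w0=0.0)
        assert np.isfinite(response_G(np.array([0.0]), rw))


class TestSolveTranslation:
    grid = np.linspace(0.0, 4.0, 400)

    def test_pure_decay(self):
        f = FunctionOnGrid(self.grid, np.zeros_like(self.grid))
        p = solve_translation(f, ProteinParams(delta=1.0, p0=1.0))
        assert np.allclose(p.values, np.exp(-self.grid), atol=1e-10)

    def test_steady_state(self):
        c, delta = 3.0, 2.0
        f = FunctionOnGrid(self.grid, np.full_like(self.grid, c))
        p = solve_translation(f, ProteinParams(delta=delta, p0=c / delta))
        assert np.allclose(p.values, c / delta, rtol=1e-4)

    def test_linear_ramp_closed_form(self):
        # f(u)=u, delta=1, p0=0 -> p(t) = t - 1 + e^{-t}; p(1)=e^{-1}
        f = FunctionOnGrid(self.grid, self.grid)
        p = solve_translation(f, ProteinParams(delta=1.0, p0=0.0))
        expected = self.grid - 1.0 + np.exp(-self.grid)
        assert np.allclose(p.values, expected, atol=1e-4)
        assert p(1.0) == pytest.approx(np.exp(-1.0), abs=1e-4)

    def test_linearity_in_driver(self, rng):
        f1 = np.abs(rng.normal(1, 0.3, self.grid.size))
        f2 = np.abs(rng.normal(2, 0.5, self.grid.size))
        pa = solve_translation(FunctionOnGrid(self.grid, f1), ProteinParams(0.7, p0=0.2))
        pb = solve_translation(FunctionOnGrid(self.grid, f2), ProteinParams(0.7, p0=0.5))
        pc = solve_translation(FunctionOnGrid(self.grid, f1 + f2), ProteinParams(0.7, p0=0.7))
        assert np.allclose(pc.values, pa.values + pb.values, atol=1e-10)

    def test_rejects_nonpositive_delta(self):
        f = FunctionOnGrid(self.grid, np.zeros_like(self.grid))
        with pytest.raises(ValueError):
            solve_translation(f, ProteinParams(delta=0.0, p0=1.0))


class TestSolveTranscription:
    def test_decoupled_linear_ode(self):
        grid = np.linspace(0.0, 6.0, 300)
        p = [FunctionOnGrid(grid, np.ones_like(grid))]
        rw = ResponseWeights(w=np.array([0.0]), w0=100.0)  # G ~ 1
        kp = KineticParams(b=1.0, s=0.0, d=1.0, a=2.0)
        m = solve_transcription(p, rw, kp)
        expected = 2.0 * np.exp(-grid) + (1.0 - np.exp(-grid))
        assert np.allclose(m, expected, atol=1e-8)

    def test_constant_response_steady_state(self):
        # w = 0 => G = 1/2 regardless of activities; m(inf) = (b + s/2)/d
        grid = np.linspace(0.0, 60.0, 2000)
        p = [FunctionOnGrid(grid, np.exp(np.sin(grid)))]
        rw = ResponseWeights(w=np.array([0.0]), w0=0.0)
        kp = KineticParams(b=0.4, s=1.0, d=0.8, a=0.0)
        m = solve_transcription(p, rw, kp)
        assert m[-1] == pytest.approx((0.4 + 0.5) / 0.8, rel=1e-3)

    @pytest.mark.parametrize("draw", range(20))
    def test_matches_adaptive_ode_integrator(self, draw):
        """Quadrature of the explicit solution vs brute-force Runge-Kutta."""
        rng = np.random.default_rng(1000 + draw)
        grid = np.linspace(0.0, 10.0, 900)
        n_tf = rng.integers(1, 4)
        fs, deltas, p0s = [], [], []
        for _ in range(n_tf):
            amp = rng.uniform(0.5, 3.0)
            centre = rng.uniform(2, 8)
            width = rng.uniform(1, 3)
            fs.append(0.1 + amp * np.exp(-0.5 * ((grid - centre) / width) ** 2))
            deltas.append(rng.uniform(0.3, 2.0))
            p0s.append(rng.uniform(0.0, 1.0))
        ps = [
            solve_translation(FunctionOnGrid(grid, f), ProteinParams(dlt, p0))
            for f, dlt, p0 in zip(fs, deltas, p0s)
        ]
        rw = ResponseWeights(w=rng.normal(0.5, 0.8, n_tf), w0=rng.normal())
        kp = KineticParams(
            b=rng.uniform(0.05, 0.5), s=rng.uniform(0.5, 2.0),
            d=rng.uniform(0.2, 2.0), a=rng.uniform(0.0, 2.0),
        )
        out_t = np.linspace(0.5, 9.5, 7)
        m_quad = solve_transcription(ps, rw, kp, out_t)

        def rhs(t, state):
            # joint integration of translation and transcription ODEs
            p_vec = np.maximum(state[:n_tf], 0.0)
            f_now = np.array([np.interp(t, grid, f) for f in fs])
            dp = f_now - np.array(deltas) * state[:n_tf]
            g = response_G(np.maximum(p_vec, 1e-8), rw)
            dm = kp.b + kp.s * g - kp.d * state[n_tf]
            return np.concatenate([dp, [dm]])

        sol = solve_ivp(
            rhs, (0.0, 10.0), np.concatenate([p0s, [kp.a]]),
            t_eval=out_t, rtol=1e-9, atol=1e-10, dense_output=False,
        )
        m_ode = sol.y[n_tf]
        assert np.allclose(m_quad, m_ode, rtol=1e-4, atol=1e-6)

    def test_grid_convergence(self):
        rng = np.random.default_rng(7)
        out_t = np.linspace(0.2, 9.8, 9)
        results = []
        for n in (400, 800):
            grid = np.linspace(0.0, 10.0, n)
            f = FunctionOnGrid(grid, 0.2 + 2 * np.exp(-0.5 * ((grid - 5) / 2) ** 2))
            p = solve_translation(f, ProteinParams(0.8, p0=0.3))
            rw = ResponseWeights(w=np.array([0.9]), w0=-0.2)
            kp = KineticParams(b=0.2, s=1.5, d=0.7, a=0.5)
            results.append(solve_transcription([p], rw, kp, out_t))
        assert np.max(np.abs(results[0] - results[1])) < 1e-4

    def test_mismatched_grids_rejected(self):
        g1 = np.linspace(0, 5, 50)
        g2 = np.linspace(0, 5, 60)
        p = [FunctionOnGrid(g1, np.ones(50)), FunctionOnGrid(g2, np.ones(60))]
        rw = ResponseWeights(w=np.array([1.0, 1.0]), w0=0.0)
        with pytest.raises(ValueError):
            solve_transcription(p, rw, KineticParams(b=1, s=1, d=1, a=0))

    def test_out_times_outside_span_rejected(self):
        grid = np.linspace(0, 5, 50)
        p = [FunctionOnGrid(grid, np.ones(50))]
        rw = ResponseWeights(w=np.array([0.0]), w0=0.0)
        with pytest.raises(ValueError):
            solve_transcription(p, rw, KineticParams(b=1, s=1, d=1, a=0), [6.0])


class TestParamValidation:
    def test_kinetics_require_positive_degradation(self):
        with pytest.raises(ValueError):
            KineticParams(b=1.0, s=1.0, d=0.0, a=0.0)

    def test_kinetics_reject_negative(self):
        with pytest.raises(ValueError):
            KineticParams(b=-0.1, s=1.0, d=1.0, a=0.0)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            FunctionOnGrid(np.array([0.0, 0.0, 1.0]), np.zeros(3))
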