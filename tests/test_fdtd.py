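"""ADE coefficients and the 1-D FDTD update.

The alpha = beta = 1 equivalence tests compare full E/P traces against
independently coded classic Drude ADE loops (written here from the
textbook update formulas, not from the package's GL machinery).
"""

import numpy as np
import pytest

from fracdrude.dispersion import FractionalDrudeMedium
from fracdrude.fdtd import (Grid1D, SourceSpec, ade_coefficients, run, step)

DRUDE = FractionalDrudeMedium(omega_p_sq=0.09, gamma_alpha=1.0,
                              gamma_beta=0.1, alpha=1.0, beta=1.0)


class TestADECoefficients:
    def test_classic_drude_values(self):
        # oracle: standard Drude ADE with gamma = 0.1, dt = 0.5:
        # P_{t+1} = [2 P_t - (1 - g dt/2) P_{t-1} + wp^2 dt^2 E]/(1 + g dt/2)
        c = ade_coefficients(DRUDE, dt=0.5, n_terms=8)
        g_half = 0.1 * 0.5 / 2
        assert c.coef_P_t == pytest.approx(2 / (1 + g_half), rel=1e-12)
        assert c.coef_P_tm1 == pytest.approx(-(1 - g_half) / (1 + g_half),
                                             rel=1e-12)
        assert c.coef_E == pytest.approx(0.09 * 0.25 / (1 + g_half),
                                         rel=1e-12)

    def test_integer_orders_have_no_memory(self):
        c = ade_coefficients(DRUDE, dt=0.5, n_terms=12)
        np.testing.assert_allclose(c.mem_alpha, 0.0, atol=1e-15)
        np.testing.assert_allclose(c.mem_beta, 0.0, atol=1e-15)
        np.testing.assert_allclose(c.history_coefs[2:], 0.0, atol=1e-15)

    def test_fractional_orders_finite_and_signed(self):
        med = FractionalDrudeMedium(omega_p_sq=0.09, alpha=0.5, beta=0.5)
        for dt in (0.05, 0.5, 1.0):
            c = ade_coefficients(med, dt, 16)
            assert np.all(np.isfinite(c.history_coefs))
            assert c.coef_E > 0

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            ade_coefficients(DRUDE, dt=-0.5, n_terms=8)
        with pytest.raises(ValueError):
            ade_coefficients(DRUDE, dt=0.5, n_terms=0)
        with pytest.raises(ValueError):
            ade_coefficients(DRUDE, dt=0.5, n_terms=8, coupling="bogus")


def reference_drude_fdtd(n_cells, dt, n_steps, src_pos, probe, omega,
                         wp_sq=0.09, gamma=0.1, ramp_cycles=10.0,
                         coupling="trapezoidal"):
    """Independent classic-Drude ADE FDTD (no GL machinery).

    Textbook recursion P_{t+1} = [2 P_t - (1 - g dt/2) P_{t-1}
    + wp^2 dt^2 * Ebar] / (1 + g dt/2) with Ebar = E^n (explicit) or
    (E^n + E^{n+1})/2 solved jointly (trapezoidal), soft sine source and
    first-order Mur ends.
    """
    E = np.zeros(n_cells)
    H = np.zeros(n_cells - 1)
    P = np.zeros(n_cells)
    Pm1 = np.zeros(n_cells)
    denom = 1 + gamma * dt / 2
    k_mur = (dt - 1) / (dt + 1)
    prev = (0.0, 0.0)
    e_trace = np.empty(n_steps)
    p_trace = np.empty(n_steps)
    ramp_time = ramp_cycles * 2 * np.pi / omega
    for n in range(n_steps):
        t = n * dt
        H += dt * (E[1:] - E[:-1])
        e_star = E.copy()
        e_star[1:-1] += dt * (H[1:] - H[:-1])
        recall = (2 * P - (1 - gamma * dt / 2) * Pm1) / denom
        if coupling == "trapezoidal":
            s = wp_sq * dt * dt / (2 * denom)
            e_new = (e_star - s * E - recall + P) / (1 + s)
            p_new = recall + s * (E + e_new)
        else:
            p_new = recall + (wp_sq * dt * dt / denom) * E
            e_new = e_star - (p_new - P)
        E = e_new
        env = (0.5 * (1 - np.cos(np.pi * t / ramp_time))
               if t < ramp_time else 1.0)
        E[src_pos] += env * np.sin(omega * t)
        E[0] = prev[0] + k_mur * (E[1] - E[0])
        E[-1] = prev[1] + k_mur * (E[-2] - E[-1])
        prev = (E[1], E[-2])
        Pm1, P = P, p_new
        e_trace[n] = E[probe]
        p_trace[n] = P[probe]
    return e_trace, p_trace


@pytest.mark.parametrize("coupling", ["trapezoidal", "explicit"])
def test_drude_limit_matches_independent_ade(coupling):
    """alpha = beta = 1 run equals the classic Drude ADE to 1e-10."""
    n_cells, dt, n_steps, omega = 400, 0.5, 2000, 0.2
    src, probe = n_cells // 2, n_cells // 2 + 5
    coeffs = ade_coefficients(DRUDE, dt, n_terms=12, coupling=coupling)
    grid = Grid1D.at_rest(n_cells, dt, 12)
    res = run(grid, coeffs, SourceSpec(position=src, omega=omega),
              n_steps, probes=(probe,))
    assert not res.diverged
    ref_e, ref_p = reference_drude_fdtd(n_cells, dt, n_steps, src, probe,
                                        omega, coupling=coupling)
    rec = res.probe(probe)
    np.testing.assert_allclose(rec.e_series, ref_e, atol=1e-10)
    np.testing.assert_allclose(rec.p_series, ref_p, atol=1e-10)


class TestStep:
    def test_vacuum_pulse_propagates_with_preserved_peak(self):
        n_cells, dt = 1200, 0.5
        vac = FractionalDrudeMedium(omega_p_sq=0.0, gamma_beta=0.0)
        coeffs = ade_coefficients(vac, dt, 4)
        grid = Grid1D.at_rest(n_cells, dt, 4,
                              medium_mask=np.zeros(n_cells, dtype=bool))
        src = SourceSpec(position=100, kind="gaussian_pulse",
                         amplitude=1.0, center_time=40.0, width=12.0)
        near, far = 150, 550          # 400 cells apart
        res = run(grid, coeffs, src, n_steps=2400, probes=(near, far))
        assert not res.diverged
        peak_near = np.max(np.abs(res.probe(near).e_series))
        peak_far = np.max(np.abs(res.probe(far).e_series))
        assert peak_far == pytest.approx(peak_near, rel=0.01)
        # propagation at speed c: peak arrives ~400 time units later
        t_near = np.argmax(np.abs(res.probe(near).e_series)) * dt
        t_far = np.argmax(np.abs(res.probe(far).e_series)) * dt
        assert t_far - t_near == pytest.approx(400.0, rel=0.02)

    def test_rest_is_a_fixed_point(self):
        coeffs = ade_coefficients(DRUDE, 0.5, 8)
        grid = Grid1D.at_rest(64, 0.5, 8)
        for _ in range(50):
            step(grid, coeffs, None)
        assert np.all(grid.E == 0)
        assert np.all(grid.H == 0)
        assert np.all(grid.p_history == 0)

    def test_causality(self):
        # changing the source amplitude from step t0 on never alters
        # anything recorded before t0
        class SwitchSource(SourceSpec):
            def __init__(self, factor, t_switch, **kw):
                super().__init__(**kw)
                self.factor = factor
                self.t_switch = t_switch

            def waveform(self, t):
                w = super().waveform(t)
                return w * self.factor if t >= self.t_switch else w

        med = FractionalDrudeMedium(omega_p_sq=0.09, alpha=0.8, beta=0.8)
        coeffs = ade_coefficients(med, 0.5, 12)
        t_switch = 300 * 0.5
        traces = []
        for factor in (1.0, 3.0):
            grid = Grid1D.at_rest(256, 0.5, 12)
            src = SwitchSource(factor, t_switch, position=128, omega=0.25)
            res = run(grid, coeffs, src, 600, probes=(132,))
            traces.append(res.probe(132))
        np.testing.assert_array_equal(traces[0].e_series[:300],
                                      traces[1].e_series[:300])
        assert not np.array_equal(traces[0].e_series[300:],
                                  traces[1].e_series[300:])

    def test_vacuum_energy_non_increasing_after_launch(self):
        n_cells, dt = 600, 0.5
        vac = FractionalDrudeMedium(omega_p_sq=0.0, gamma_beta=0.0)
        coeffs = ade_coefficients(vac, dt, 4)
        grid = Grid1D.at_rest(n_cells, dt, 4,
                              medium_mask=np.zeros(n_cells, dtype=bool))
        src = SourceSpec(position=300, kind="gaussian_pulse",
                         center_time=30.0, width=8.0)
        # launch the pulse
        for _ in range(200):
            step(grid, coeffs, src)
        energies = []
        for _ in range(20):
            for _ in range(25):
                step(grid, coeffs, None)
            energies.append(0.5 * np.sum(grid.E ** 2)
                            + 0.5 * np.sum(grid.H ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))


class TestRunDivergence:
    def _diverges(self, medium, dt, n_steps=6000, omega=0.2):
        coeffs = ade_coefficients(medium, dt, 12)
        grid = Grid1D.at_rest(512, dt, 12)
        res = run(grid, coeffs, SourceSpec(position=256, omega=omega),
                  n_steps, probes=(260,))
        return res.diverged

    def test_courant_violation_diverges(self):
        assert self._diverges(DRUDE, dt=1.1)

    def test_alpha_two_diverges(self):
        med = FractionalDrudeMedium(omega_p_sq=0.09, alpha=2.0, beta=1.0)
        assert self._diverges(med, dt=0.5)

    def test_beta_two_is_stable(self):
        med = FractionalDrudeMedium(omega_p_sq=0.09, alpha=1.0, beta=2.0)
        assert not self._diverges(med, dt=0.5)

    def test_probe_outside_grid(self):
        coeffs = ade_coefficients(DRUDE, 0.5, 8)
        grid = Grid1D.at_rest(64, 0.5, 8)
        with pytest.raises(IndexError):
            run(grid, coeffs, SourceSpec(position=32, omega=0.2), 10,
                probes=(64,))
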