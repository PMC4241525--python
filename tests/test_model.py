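import numpy as np
import pytest

from rbpregulon import (
    GeneKinetics,
    SystemParameters,
    closed_form_trajectory,
    draw_kinetics,
    integrate_tg,
    model_oracle_fixture,
    rbp_level_grid,
    simulate_rep,
    steady_state,
    sweep_phase_diagram,
)
from rbpregulon.model import PARAM_SPACES, _correlate_rows


def random_draw(rng):
    p = {k: rng.uniform(lo, hi) for k, (lo, hi) in PARAM_SPACES.items()}
    g = GeneKinetics(A=p["A"], T=p["T"], n=p["n"], k=p["k"], tg0=p["tg0"])
    return g, rng.uniform(0, 2), rng.uniform(0, 2), rng.uniform(0, 1)  # rbp, m, j


class TestSteadyState:
    def test_closed_form_half(self):
        g = GeneKinetics(A=1, T=1, n=1, k=0.5, tg0=0.3)
        assert steady_state(g, rbp=1, m=1, j=0.5) == pytest.approx(0.5)

    def test_j_zero_independent_of_rbp_given_fixed_tf(self):
        g = GeneKinetics(A=1.5, T=2.0, n=2.0, k=0.4, tg0=0.1)
        # with j=0 the rbp level only enters through TF = m*rbp; fix TF=1
        a = steady_state(g, rbp=1.0, m=1.0, j=0.0)
        b = steady_state(g, rbp=2.0, m=0.5, j=0.0)
        assert a == pytest.approx(b)
        hill = 1.0 / (2.0**2 + 1.0)
        assert a == pytest.approx(1.5 * hill / 0.4)

    def test_saturation_limit_small_threshold(self):
        g = GeneKinetics(A=1.8, T=1e-9, n=2.0, k=0.5, tg0=0.1)
        assert steady_state(g, rbp=1.0, m=1.0, j=0.5) == pytest.approx(
            1.8 / (0.5 + 0.5), rel=1e-6
        )

    def test_monotone_in_parameters(self, rng):
        g, rbp, m, j = random_draw(rng)
        base = steady_state(g, rbp, m, j)
        assert steady_state(g, rbp, m, j + 0.1) < base
        stiffer = GeneKinetics(A=g.A, T=g.T, n=g.n, k=g.k + 0.1, tg0=g.tg0)
        assert steady_state(stiffer, rbp, m, j) < base
        brighter = GeneKinetics(A=g.A + 0.1, T=g.T, n=g.n, k=g.k, tg0=g.tg0)
        assert steady_state(brighter, rbp, m, j) > base

    def test_matches_independent_rational_oracle(self):
        fixture = model_oracle_fixture(seed=7)
        for row in fixture.itertuples():
            got = steady_state(row.kinetics, row.rbp, row.m, row.j)
            assert got == pytest.approx(row.steady_state, abs=1e-12)


class TestIntegration:
    def test_integrator_matches_exponential_closed_form(self, rng):
        for _ in range(20):
            g, rbp, m, j = random_draw(rng)
            rate = g.k + j * rbp
            t_end = 50.0 / rate
            dt = t_end / 100
            traj = integrate_tg(g, rbp, m, j, t_end=t_end, dt=dt)
            t = np.arange(0.0, t_end + 0.5 * dt, dt)
            exact = closed_form_trajectory(g, rbp, m, j, t)
            assert np.abs(traj - exact).max() < 1e-6
            assert abs(traj[-1] - steady_state(g, rbp, m, j)) < 1e-6

    def test_fixed_point_stays_constant(self):
        g0 = GeneKinetics(A=1.5, T=1.0, n=2.0, k=0.5, tg0=0.0)
        ss = steady_state(g0, 1.0, 1.0, 0.5)
        g = GeneKinetics(A=1.5, T=1.0, n=2.0, k=0.5, tg0=ss)
        traj = integrate_tg(g, 1.0, 1.0, 0.5, t_end=10.0, dt=0.1)
        assert np.abs(traj - ss).max() < 1e-8

    def test_no_overshoot(self, rng):
        g, rbp, m, j = random_draw(rng)
        traj = integrate_tg(g, rbp, m, j, t_end=20.0, dt=0.05)
        ss = steady_state(g, rbp, m, j)
        lo, hi = min(g.tg0, ss), max(g.tg0, ss)
        assert (traj >= lo - 1e-9).all() and (traj <= hi + 1e-9).all()
        diffs = np.diff(traj)
        assert (diffs >= -1e-9).all() or (diffs <= 1e-9).all()

    def test_bad_time_arguments_rejected(self):
        g = GeneKinetics(A=1.5, T=1.0, n=2.0, k=0.5, tg0=0.1)
        with pytest.raises(ValueError):
            integrate_tg(g, 1.0, 1.0, 0.5, t_end=-1.0, dt=0.1)


class TestSampling:
    def test_draws_respect_open_intervals(self, rng):
        draws = draw_kinetics(rng, 100_000)
        for name, (lo, hi) in PARAM_SPACES.items():
            assert draws[name].min() > lo
            assert draws[name].max() < hi
        assert (draws["tg0"] < draws["A"]).all()

    def test_rbp_grid_strictly_inside(self):
        grid = rbp_level_grid(1000)
        assert grid.min() > 0.0 and grid.max() < 2.0
        assert len(grid) == 1000


class TestSimulateRep:
    def test_fixed_seed_reproducible(self):
        params = SystemParameters(n_genes=50, n_rbp_levels=100, n_reps=1, seed=9)
        a = simulate_rep(params, m=1.0, j=0.5)
        b = simulate_rep(params, m=1.0, j=0.5)
        assert a == b

    def test_j_zero_high_m_gives_positive_mean_correlation(self):
        params = SystemParameters(n_genes=100, n_rbp_levels=100, n_reps=1, seed=3)
        out = simulate_rep(params, m=1.5, j=0.0)
        assert out["rho_mean"] > 0

    def test_constant_rows_are_degenerate(self):
        rows = np.vstack([np.ones(5), np.arange(5.0)])
        rho = _correlate_rows(rows, np.arange(5.0), "pearson")
        assert np.isnan(rho[0]) and rho[1] == pytest.approx(1.0)


class TestSweep:
    def test_small_sweep_structure_and_determinism(self):
        params = SystemParameters(
            n_genes=50, n_rbp_levels=100, n_reps=50, seed=21
        )
        gm, gj = [0.3, 1.7], [0.1, 0.9]
        a = sweep_phase_diagram(gm, gj, params)
        b = sweep_phase_diagram(gm, gj, params)
        assert a.equals(b)
        assert len(a) == 4
        assert a.region.nunique() >= 2
        corner = a[(a.m == 1.7) & (a.j == 0.1)].iloc[0]
        assert corner.region == "pos_mean_neg_cd"

    def test_grid_outside_spaces_rejected(self):
        params = SystemParameters(n_genes=10, n_rbp_levels=10, n_reps=1, seed=0)
        with pytest.raises(ValueError):
            sweep_phase_diagram([2.5], [0.5], params)
        with pytest.raises(ValueError):
            sweep_phase_diagram([1.0], [1.5], params)


class TestOracleFixture:
    def test_reference_half_case(self):
        g = GeneKinetics(A=1, T=1, n=1, k=0.5, tg0=0.3)
        assert steady_state(g, 1.0, 1.0, 0.5) == pytest.approx(0.5)

    def test_fixture_values_finite_positive(self):
        fixture = model_oracle_fixture(seed=0)
        assert len(fixture) <= 10
        assert (fixture.steady_state > 0).all()
        assert np.isfinite(fixture.steady_state).all()

    def test_fixture_deterministic(self):
        a = model_oracle_fixture(seed=5)
        b = model_oracle_fixture(seed=5)
        assert (a.steady_state == b.steady_state).all()
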