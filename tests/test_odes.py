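"""Kinetic equations: closed forms, oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from lineageflux.topology import Compartment, DifferentiationEdge, LineageTopology
from lineageflux.odes import (
    RateSet,
    StateVector,
    assemble_odes,
    gfp_to_divisions,
    integrate,
    matrix_exponential,
    predict_observables,
    steady_state_sizes,
)
from lineageflux.odes import RateError


def single_compartment(p=0.1, delta=0.0):
    topo = LineageTopology(
        [Compartment("c", level=0, column="x", is_tip=True, allows_loss=True)], []
    )
    rates = RateSet(alpha={}, p={"c": p}, delta={"c": delta},
                    N0={"c": 1.0}, f0={"c": 1.0})
    return topo, rates


def chain(alpha=0.05, p_a=0.0, d_a=0.0, beta=0.0, n_tip=1.0, f_tip=0.4, p_tip=None):
    """tip -> a, with tip demographically balanced (p_tip = alpha)."""
    topo = LineageTopology(
        [Compartment("tip", level=0, column="x", is_tip=True),
         Compartment("a", level=1, column="x", allows_loss=True)],
        [DifferentiationEdge("tip", "a")],
    )
    d = steady_state_sizes(topo, RateSet(
        alpha={("tip", "a"): alpha}, p={"tip": alpha if p_tip is None else p_tip,
                                        "a": p_a},
        delta={"a": d_a + beta}, N0={"tip": n_tip}, f0={"tip": f_tip}))
    rates = RateSet(alpha={("tip", "a"): alpha},
                    p={"tip": alpha if p_tip is None else p_tip, "a": p_a},
                    delta={"a": d_a + beta},
                    N0={k: v for k, v in d.sizes.items()}, f0={"tip": f_tip})
    return topo, rates


class TestClosedForms:
    def test_exponential_growth_and_gfp_mean_decay(self):
        # closed dividing compartment: N = N0 e^{pt}, total GFP constant,
        # population-mean GFP content decays as e^{-pt}
        topo, rates = single_compartment(p=0.25)
        t = np.array([0.0, 1.0, 4.0, 10.0])
        traj = integrate(assemble_odes(topo, rates), t)
        assert np.allclose(traj.N[:, 0], np.exp(0.25 * t), rtol=1e-10)
        assert np.allclose(traj.G[:, 0], 1.0, rtol=1e-10)
        pred = predict_observables(traj)
        assert np.allclose(pred.g[:, 0], np.exp(-0.25 * t), rtol=1e-9)

    def test_label_equilibration_closed_form(self):
        # downstream compartment at steady state approaches the tip label as
        # f_a(t) = f_tip (1 - exp(-(alpha N_tip / N_a) t))
        alpha, beta, f_tip = 0.05, 0.4, 0.4
        topo, rates = chain(alpha=alpha, beta=beta, f_tip=f_tip)
        lam = alpha * rates.N0["tip"] / rates.N0["a"]
        assert lam == pytest.approx(beta)  # flux balance fixes the timescale
        t = np.linspace(0, 30, 10)
        pred = predict_observables(integrate(assemble_odes(topo, rates), t))
        f_a = pred.f[:, pred.ids.index("a")]
        assert np.allclose(f_a, f_tip * (1 - np.exp(-lam * t)), rtol=1e-8, atol=1e-12)

    def test_total_cell_number_balance(self, toy):
        # differentiation edges conserve total cell number:
        # d(sum N)/dt = sum (p_i - delta_i) N_i, i.e. column sums of the
        # operator equal p - delta exactly
        topo, rates = toy
        sys_ = assemble_odes(topo, rates)
        col_sums = sys_.matrix.sum(axis=0)
        assert np.allclose(col_sums, sys_.p - sys_.delta, atol=1e-14)

    def test_gfp_divisions_mapping(self):
        assert gfp_to_divisions(1.0) == 0.0
        assert gfp_to_divisions(0.25) == pytest.approx(2.0)
        assert gfp_to_divisions(0.1) == pytest.approx(3.3219, abs=1e-4)
        with pytest.raises(ValueError):
            gfp_to_divisions(0.0)
        with pytest.raises(ValueError):
            gfp_to_divisions(1.2)


class TestIntegrate:
    def test_identity_at_t0(self, toy):
        topo, rates = toy
        sys_ = assemble_odes(topo, rates)
        init = sys_.initial_state()
        traj = integrate(sys_, np.array([0.0]))
        assert np.array_equal(traj.N[0], init.N)
        assert np.array_equal(traj.L[0], init.L)

    def test_against_stiff_ivp_oracle(self, toy):
        topo, rates = toy
        sys_ = assemble_odes(topo, rates)
        init = sys_.initial_state()
        t = np.array([0.0, 3, 14, 56, 168.0])
        traj = integrate(sys_, t)
        sol = solve_ivp(lambda tt, x: sys_.matrix @ x, (0, 168), init.N,
                        t_eval=t, rtol=1e-10, atol=1e-14, method="LSODA")
        assert np.max(np.abs(traj.N - sol.y.T) / np.abs(sol.y.T)) < 1e-6

    def test_matrix_exponential_on_defective_operator(self):
        # two compartments with identical net turnover form a Jordan block;
        # compare against a high-accuracy explicit Runge-Kutta solve
        A = np.array([[0.0, 0.0, 0.0],
                      [0.01, -0.1, 0.0],
                      [0.0, 0.05, -0.1]])
        x0 = np.array([1.0, 0.02, 0.01])
        for t in (7.0, 56.0, 168.0):
            ref = solve_ivp(lambda tt, x: A @ x, (0, t), x0, rtol=1e-12,
                            atol=1e-16, method="DOP853").y[:, -1]
            got = matrix_exponential(A * t) @ x0
            assert np.max(np.abs(got - ref) / np.abs(ref)) < 1e-9

    def test_bad_grid_and_bad_state(self, toy):
        topo, rates = toy
        sys_ = assemble_odes(topo, rates)
        with pytest.raises(ValueError):
            integrate(sys_, np.array([1.0, 2.0]))  # must start at 0
        with pytest.raises(ValueError):
            integrate(sys_, np.array([0.0, 2.0, 1.0]))
        bad = StateVector(N=np.ones(5), L=2 * np.ones(5), G=np.ones(5))
        with pytest.raises(ValueError, match="L"):
            integrate(sys_, np.array([0.0, 1.0]), bad)

    def test_negative_rate_rejected(self, toy):
        topo, rates = toy
        broken = RateSet(alpha=dict(rates.alpha), p=dict(rates.p),
                         delta=dict(rates.delta), N0=dict(rates.N0),
                         f0=dict(rates.f0))
        broken.p["A1"] = -0.1
        with pytest.raises(RateError, match="negative"):
            assemble_odes(topo, broken)

    def test_missing_edge_rate_named(self, toy):
        topo, rates = toy
        broken = RateSet(alpha={k: v for k, v in rates.alpha.items()
                                if k != ("A1", "B2")},
                         p=dict(rates.p), delta=dict(rates.delta),
                         N0=dict(rates.N0), f0=dict(rates.f0))
        with pytest.raises(RateError, match="A1->B2"):
            assemble_odes(topo, broken)


class TestObservables:
    def test_full_labelling_gives_unit_fraction(self, toy):
        topo, rates = toy
        full = RateSet(alpha=dict(rates.alpha), p=dict(rates.p),
                       delta=dict(rates.delta), N0=dict(rates.N0),
                       f0={c: 1.0 for c in topo.ids})
        pred = predict_observables(integrate(assemble_odes(topo, full),
                                             np.linspace(0, 100, 6)))
        assert np.allclose(pred.f, 1.0, atol=1e-9)

    def test_no_divisions_gives_unit_retention(self, toy):
        topo, rates = toy
        frozen = RateSet(alpha=dict(rates.alpha), p={c: 0.0 for c in topo.ids},
                         delta=dict(rates.delta), N0=dict(rates.N0),
                         f0=dict(rates.f0))
        pred = predict_observables(integrate(assemble_odes(topo, frozen),
                                             np.linspace(0, 50, 5)))
        assert np.allclose(pred.g, 1.0, atol=1e-9)

    def test_vanishing_population_flagged_nan(self):
        topo = LineageTopology(
            [Compartment("tip", level=0, column="x", is_tip=True),
             Compartment("a", level=1, column="x", observed=False)],
            [DifferentiationEdge("tip", "a")],
        )
        rates = RateSet(alpha={("tip", "a"): 0.0}, p={}, delta={},
                        N0={"tip": 1.0, "a": 0.0}, f0={"tip": 0.5})
        pred = predict_observables(integrate(assemble_odes(topo, rates),
                                             np.array([0.0, 1.0])))
        assert np.isnan(pred.f[:, 1]).all()


class TestSteadyState:
    def test_chain_flux_balance(self):
        topo, rates = chain(alpha=0.05, beta=0.4, n_tip=2.0)
        ss = steady_state_sizes(topo, rates)
        assert not ss.diverged
        assert ss.sizes["a"] == pytest.approx(0.05 * 2.0 / 0.4)

    def test_divergence_flagged(self):
        topo, rates = chain(alpha=0.05, beta=0.1, p_a=0.5)
        ss = steady_state_sizes(topo, rates)
        assert ss.diverged
        assert ss.dominant_eigenvalue >= 0

    def test_matches_long_time_integration(self, toy):
        topo, rates = toy
        ss = steady_state_sizes(topo, rates)
        start = RateSet(alpha=dict(rates.alpha), p=dict(rates.p),
                        delta=dict(rates.delta),
                        N0={c: (rates.N0[c] * (2.0 if c != "S" else 1.0))
                            for c in topo.ids},
                        f0=dict(rates.f0))
        traj = integrate(assemble_odes(topo, start), np.array([0.0, 2000.0]))
        final = dict(zip(traj.ids, traj.N[-1]))
        for cid, v in ss.sizes.items():
            assert final[cid] == pytest.approx(v, rel=1e-6)


class TestInvariantProperties:
    def test_label_neutrality(self, toy):
        # equal label fractions everywhere stay equal for all time
        topo, rates = toy
        r = RateSet(alpha=dict(rates.alpha), p=dict(rates.p),
                    delta=dict(rates.delta), N0=dict(rates.N0),
                    f0={c: 0.37 for c in topo.ids})
        pred = predict_observables(integrate(assemble_odes(topo, r),
                                             np.linspace(0, 200, 9)))
        assert np.max(np.abs(pred.f - 0.37)) < 1e-10

    def test_tip_label_constancy(self, toy):
        topo, rates = toy
        t = np.linspace(0, 300, 11)
        pred = predict_observables(integrate(assemble_odes(topo, rates), t))
        f_tip = pred.f[:, pred.ids.index("S")]
        assert np.max(np.abs(f_tip - rates.f0["S"])) < 1e-12

    def test_label_equilibration_monotone_to_source(self, toy):
        # over 10x the slowest timescale every fraction approaches the tip's
        topo, rates = toy
        sys_ = assemble_odes(topo, rates)
        slowest = 1.0 / 0.015  # tip turnover sets the slowest scale here
        t = np.linspace(0, 10 * slowest, 400)
        pred = predict_observables(integrate(sys_, t))
        f_star = rates.f0["S"]
        for j, cid in enumerate(pred.ids):
            f = pred.f[:, j]
            assert abs(f[-1] - f_star) < 1e-3
            tail = f[t > 30]  # past the initial transient
            assert np.all(np.diff(np.abs(tail - f_star)) <= 1e-12)

    def test_gfp_conservation_closed_system(self):
        topo = LineageTopology(
            [Compartment("tip", level=0, column="x", is_tip=True),
             Compartment("a", level=1, column="x")],
            [DifferentiationEdge("tip", "a")],
        )
        rates = RateSet(alpha={("tip", "a"): 0.1}, p={"tip": 0.3, "a": 0.2},
                        delta={}, N0={"tip": 1.0, "a": 0.5}, f0={"tip": 0.2})
        traj = integrate(assemble_odes(topo, rates), np.linspace(0, 40, 9))
        total = traj.G.sum(axis=1)
        assert np.allclose(total, total[0], rtol=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_state_bounds_under_random_rates(self, toy, seed):
        topo, _ = toy
        rng = np.random.default_rng(seed)
        alpha = {e.key(): float(10 ** rng.uniform(-3, 0)) for e in topo.edges}
        rates = RateSet(
            alpha=alpha,
            p={c.id: float(10 ** rng.uniform(-3, 0))
               for c in topo.compartments if c.allows_proliferation},
            delta={c.id: float(10 ** rng.uniform(-2, 0.5))
                   for c in topo.compartments if c.allows_loss},
            N0={c.id: float(10 ** rng.uniform(-3, 0)) for c in topo.compartments},
            f0={"S": float(rng.uniform(0, 1))},
        )
        traj = integrate(assemble_odes(topo, rates), np.linspace(0, 60, 7))
        assert np.all(traj.N >= -1e-9)
        assert np.all(traj.G >= -1e-9)
        assert np.all(traj.L <= traj.N * (1 + 1e-7) + 1e-12)
        assert np.all(traj.L >= -1e-9)
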