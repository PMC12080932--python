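"""Kinetic Monte Carlo: rate formulas, selection statistics, insertion."""

import numpy as np
import pytest

from thrombosim.flow import solve_flow
from thrombosim.geometry import DomainSpec, build_domain
from thrombosim.kmc import (KMCParams, QuiescentState, RateDatabase,
                            bond_rates, inlet_insertion_profile,
                            insert_inlet_platelets, motion_rates,
                            select_execute, vwf_factor)


class TestMotionRates:
    def test_pure_diffusion_is_isotropic(self):
        r = motion_rates(np.zeros(2), D_p=25.0, dx=5.0)
        assert np.allclose(r, 25.0 / 25.0)

    def test_upwind_convection_adds_to_forward_rate_only(self):
        r = motion_rates(np.array([100.0, 0.0]), D_p=25.0, dx=5.0)
        base = 1.0
        assert r[0] == pytest.approx(base + 100.0 / 5.0)
        assert np.allclose(r[1:], base)

    def test_blocked_directions_are_zero(self):
        r = motion_rates(np.array([100.0, -40.0]), 25.0, 5.0,
                         blocked=[True, False, False, True])
        assert r[0] == 0.0 and r[3] == 0.0      # blocked faces
        assert r[1] == pytest.approx(1.0)       # diffusion only against flow
        assert r[2] == pytest.approx(1.0)       # u_y < 0: no +y convection

    def test_fully_caged_platelet_cannot_move(self):
        r = motion_rates(np.array([50.0, 50.0]), 25.0, 5.0,
                         blocked=[True] * 4)
        assert not r.any()


def run_walk(rates_fn, n_events, seed):
    """Single-particle KMC driver on an unbounded lattice."""
    rng = np.random.default_rng(seed)
    pos = np.zeros(2)
    t = 0.0
    db = RateDatabase()
    moves = {"hop+x": (1, 0), "hop-x": (-1, 0),
             "hop+y": (0, 1), "hop-y": (0, -1)}
    for _ in range(n_events):
        rates = rates_fn()
        db.set_events(0, [("hop+x", rates[0]), ("hop-x", rates[1]),
                          ("hop+y", rates[2]), ("hop-y", rates[3])])
        ev, dt = select_execute(db, rng)
        pos += moves[ev.kind]
        t += dt
    return pos, t


class TestEinsteinAndDrift:
    def test_msd_recovers_diffusivity(self):
        # MSD/t -> 2 d D for an unbiased walk (Einstein relation)
        D, dx = 25.0, 5.0
        rates = motion_rates(np.zeros(2), D, dx)
        disps = []
        times = []
        for k in range(40):
            pos, t = run_walk(lambda: rates, 250, seed=k)
            disps.append((pos * dx) @ (pos * dx))
            times.append(t)
        D_est = np.mean(disps) / np.mean(times) / 4.0  # 2 d D, d = 2
        assert D_est == pytest.approx(D, rel=0.05)

    def test_mean_drift_speed_matches_flow(self):
        D, dx, ux = 25.0, 5.0, 200.0
        rates = motion_rates(np.array([ux, 0.0]), D, dx)
        xs, ts = [], []
        for k in range(40):
            pos, t = run_walk(lambda: rates, 250, seed=1000 + k)
            xs.append(pos[0] * dx)
            ts.append(t)
        assert np.sum(xs) / np.sum(ts) == pytest.approx(ux, rel=0.05)


class TestSelection:
    def test_selection_frequencies_proportional_to_rates(self):
        rng = np.random.default_rng(5)
        db = RateDatabase()
        db.set_events(0, [("a", 1.0)])
        db.set_events(1, [("b", 3.0)])
        n = 100_000
        hits = sum(select_execute(db, rng)[0].kind == "a" for _ in range(n))
        p = 0.25
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sigma

    def test_waiting_times_are_exponential(self):
        rng = np.random.default_rng(6)
        lam = 4.0
        db = RateDatabase()
        db.set_events(0, [("e", lam)])
        dts = np.array([select_execute(db, rng)[1] for _ in range(100_000)])
        assert dts.mean() == pytest.approx(1.0 / lam, rel=0.02)

    def test_fixed_seed_reproduces_event_sequence(self):
        def seq(seed):
            rng = np.random.default_rng(seed)
            db = RateDatabase()
            db.set_events(0, [("a", 1.0), ("b", 2.0)])
            return [(select_execute(db, rng)[0].kind,
                     select_execute(db, rng)[1]) for _ in range(200)]
        assert seq(42) == seq(42)
        assert seq(42) != seq(43)

    def test_empty_catalog_signals_quiescence(self):
        with pytest.raises(QuiescentState):
            select_execute(RateDatabase(), np.random.default_rng(0))

    def test_total_rate_tracks_entries(self):
        db = RateDatabase()
        db.set_events(3, [("a", 1.5), ("b", 2.5)])
        db.set_events(9, [("c", 1.0)])
        assert db.total_rate == pytest.approx(5.0, rel=1e-12)
        db.remove(3)
        assert db.total_rate == pytest.approx(1.0, rel=1e-12)


class TestTwoStateOccupancy:
    def test_long_run_occupancy_matches_analytic_fraction(self):
        # attach/detach two-state chain: P(bound) = a / (a + d)
        a, d = 3.0, 1.0
        rng = np.random.default_rng(7)
        db = RateDatabase()
        bound = False
        t_bound = t_total = 0.0
        for _ in range(200_000):
            db.set_events(0, [("detach" if bound else "attach",
                               d if bound else a)])
            ev, dt = select_execute(db, rng)
            t_total += dt
            if bound:
                t_bound += dt
            bound = ev.kind == "attach"
        assert t_bound / t_total == pytest.approx(a / (a + d), rel=0.02)


class TestBondRates:
    def test_zero_shear_baseline(self):
        p = KMCParams()
        att, det = bond_rates(p_alpha_min(), 0.0, p)
        assert att == pytest.approx(p.k_att_pp * p_alpha_min())
        assert det == pytest.approx(p.k_det_pp / p_alpha_min())

    def test_collagen_prefactors_differ(self):
        p = KMCParams()
        att_c, det_c = bond_rates(0.5, 100.0, p, collagen=True)
        att_p, det_p = bond_rates(0.5, 100.0, p, collagen=False)
        assert att_c / att_p == pytest.approx(p.k_att_col / p.k_att_pp)
        assert det_c / det_p == pytest.approx(p.k_det_col / p.k_det_pp)

    def test_vwf_factor_monotone_with_midpoint_in_window(self):
        p = KMCParams()
        g = np.linspace(0, 20000, 400)
        W = vwf_factor(g, p)
        assert (np.diff(W) >= 0).all() and (W >= 1).all()
        mid = 1 + (p.w_max - 1) / 2
        g_mid = g[np.argmin(np.abs(W - mid))]
        assert 3000.0 <= g_mid <= 8000.0

    def test_detachment_is_slip_bond(self):
        p = KMCParams()
        _, d1 = bond_rates(0.5, 0.0, p)
        _, d2 = bond_rates(0.5, p.gamma_c, p)
        assert d2 / d1 == pytest.approx(np.e)

    def test_adhesiveness_outside_hill_bounds_rejected(self):
        with pytest.raises(ValueError):
            bond_rates(1.7, 100.0, KMCParams())


def p_alpha_min():
    return 0.01


@pytest.fixture(scope="module")
def inlet_setup():
    spec = DomainSpec(shape="cylinder", length=0.12, inlet_diameter=0.12,
                      collagen_patch_length=0.0, lattice_spacing=6.0,
                      dimensionality=2)
    grid = build_domain(spec)
    _, vel = solve_flow(grid, None, 200.0)
    return grid, vel


class TestInsertion:
    def test_uniform_limit_rate_is_cbulk_times_q(self, inlet_setup):
        grid, vel = inlet_setup
        params = KMCParams(margination_excess=1.0)
        _, _, rate, Q = inlet_insertion_profile(grid, vel, params)
        assert rate == pytest.approx(params.c_bulk * 1e-9 * Q, rel=1e-12)

    def test_mixing_cup_concentration_recovered(self, inlet_setup):
        # flux-weighted average of inserted platelets over a long window
        grid, vel = inlet_setup
        params = KMCParams()  # margination on, no band restriction
        _, _, rate, Q = inlet_insertion_profile(grid, vel, params)
        rng = np.random.default_rng(3)
        T = 100_000 / rate
        n = rng.poisson(rate * T)
        c_emp = n / (Q * T) * 1e9  # back to μL⁻¹
        assert c_emp == pytest.approx(params.c_bulk, rel=0.03)

    def test_margination_weights_peak_at_wall(self, inlet_setup):
        grid, vel = inlet_setup
        nodes, w, _, _ = inlet_insertion_profile(grid, vel, KMCParams())
        r = grid.radial_distance()[0][grid.lumen_mask()[0]]
        # concentration factor rises toward the wall even though the
        # flux factor u(r) falls there
        c_over_u = w / np.clip(vel[0][0][grid.lumen_mask()[0]], 1e-9, None)
        assert c_over_u[np.argmax(r)] > 2.0 * c_over_u[np.argmin(r)]

    def test_zero_window_inserts_nothing(self, inlet_setup):
        grid, vel = inlet_setup
        rng = np.random.default_rng(0)
        assert insert_inlet_platelets(grid, vel, 0.0, rng, KMCParams()) == []

    def test_insertions_land_on_inlet_lumen(self, inlet_setup):
        grid, vel = inlet_setup
        rng = np.random.default_rng(1)
        nodes = insert_inlet_platelets(grid, vel, 0.5, rng, KMCParams())
        assert len(nodes) > 0
        for node in nodes:
            assert node[0] == 0
            assert grid.lumen_mask()[node]

    def test_band_restriction_zeroes_core_weights(self, inlet_setup):
        grid, vel = inlet_setup
        nodes, w, rate_band, _ = inlet_insertion_profile(
            grid, vel, KMCParams(insertion_band=12.0))
        _, _, rate_full, _ = inlet_insertion_profile(grid, vel, KMCParams())
        r = grid.radial_distance()[0][grid.lumen_mask()[0]]
        R = grid.spec.inlet_diameter * 1e3 / 2.0
        assert (w[R - r > 12.0] == 0).all()
        assert 0 < rate_band < rate_full


class TestEngineConsistency:
    def test_engine_rates_match_module_formulas(self):
        """The production event loop computes the same rates as the
        platelet-level operations."""
        from thrombosim import engine
        from thrombosim.transport import axis_neighbor_table

        p = KMCParams()
        shape = (8, 6)
        nn = 48
        dx = 6.0
        solid = np.zeros(shape, bool)
        solid[:, 0] = solid[:, -1] = True
        nbr = axis_neighbor_table(shape).copy()
        for d in range(4):
            col = nbr[:, d]
            col[(col >= 0) & solid.ravel()[np.clip(col, 0, nn - 1)]] = -1
        nbr[solid.ravel()] = -1
        u = np.array([300.0, -50.0])
        hop = np.zeros((nn, 4))
        hop[:, 0] = p.D_p / dx**2 + max(0, u[0]) / dx
        hop[:, 1] = p.D_p / dx**2 + max(0, -u[0]) / dx
        hop[:, 2] = p.D_p / dx**2 + max(0, u[1]) / dx
        hop[:, 3] = p.D_p / dx**2 + max(0, -u[1]) / dx
        hop[nbr == -1] = 0.0
        gamma = 1500.0
        W = np.asarray(vwf_factor(np.full(nn, gamma), p))
        edet = np.exp(np.full(nn, gamma) / p.gamma_c)
        col_adj = np.zeros(nn, bool)
        idx = np.arange(nn).reshape(shape)
        col_adj[idx[4, 1]] = True          # mobile platelet touching collagen
        occ = np.full(nn, -1, np.int64)
        bound_node = np.zeros(nn, bool)
        pos = np.array([idx[4, 1], idx[4, 2]], np.int64)
        status = np.array([1, 2], np.int8)
        F = np.array([0.3, 0.8])
        colbound = np.array([False, False])
        occ[pos[0]] = 0
        occ[pos[1]] = 1
        bound_node[pos[1]] = True

        got_mobile = engine._mobile_rate(0, pos, F, occ, bound_node, col_adj,
                                         hop, W, nbr, p.k_att_col, p.k_att_pp)
        # +y neighbor occupied by the bound platelet; -y is the wall
        mr = motion_rates(u, p.D_p, dx, blocked=[False, False, True, True])
        att_col, _ = bond_rates(F[0], gamma, p, collagen=True)
        att_pp, _ = bond_rates(max(F[0], F[1]), gamma, p, collagen=False)
        assert got_mobile == pytest.approx(mr.sum() + att_col + att_pp)

        got_detach = engine._detach_rate(1, pos, F, colbound, edet,
                                         p.k_det_col, p.k_det_pp)
        _, det = bond_rates(F[1], gamma, p, collagen=False)
        assert got_detach == pytest.approx(det)
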