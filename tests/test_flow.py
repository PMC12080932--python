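"""Lattice Boltzmann flow: Poiseuille benchmarks, shear field, occlusion."""

import numpy as np
import pytest

from thrombosim.flow import (FlowParams, _macroscopic, _stencil, solve_flow,
                             update_noslip, wall_shear)
from thrombosim.geometry import ConfigurationError, DomainSpec, build_domain


def small_channel(dx=6.0, length=0.12, diameter=0.06):
    spec = DomainSpec(shape="cylinder", length=length,
                      inlet_diameter=diameter, collagen_patch_length=0.0,
                      lattice_spacing=dx, dimensionality=2)
    return build_domain(spec)


@pytest.fixture(scope="module")
def channel_solution():
    grid = small_channel()
    state, vel = solve_flow(grid, None, 200.0)
    return grid, state, vel


def mass_flux_per_column(grid, state, vel, occ=None):
    c, _ = _stencil(grid.dim)
    rho, _ = _macroscopic(state.f, c)
    rho = rho.reshape(grid.shape)
    lum = grid.lumen_mask()
    if occ is not None:
        lum = lum & ~occ
    return np.array([(rho[i][lum[i]] * vel[0][i][lum[i]]).sum()
                     for i in range(grid.nx)])


class TestPoiseuille:
    def test_centerline_velocity(self, channel_solution):
        grid, _, vel = channel_solution
        # u_max = gamma_w R / 2 for the imposed wall shear rate
        R = grid.spec.inlet_diameter * 1e3 / 2.0
        assert vel[0][grid.nx // 2].max() == pytest.approx(
            200.0 * R / 2.0, rel=0.05)

    def test_wall_shear_recovers_inlet_value(self, channel_solution):
        grid, _, vel = channel_solution
        gamma = wall_shear(vel, grid)
        mid = grid.nx // 2
        near_wall = gamma[mid][grid.lumen_mask()[mid]]
        assert near_wall[0] == pytest.approx(200.0, rel=0.05)
        assert near_wall[-1] == pytest.approx(200.0, rel=0.05)

    def test_mass_conservation_along_channel(self, channel_solution):
        grid, state, vel = channel_solution
        # compare the first and last interior cross-sections (the BC
        # columns impose profile/pressure rather than a developed flow)
        flux = mass_flux_per_column(grid, state, vel)
        assert flux[-2] == pytest.approx(flux[1], rel=0.01)

    def test_density_deviation_below_one_percent(self, channel_solution):
        grid, state, _ = channel_solution
        c, _ = _stencil(grid.dim)
        rho, _ = _macroscopic(state.f, c)
        assert np.abs(rho[~state.solid] - 1.0).max() < 0.01

    def test_velocity_zero_on_solid(self, channel_solution):
        grid, _, vel = channel_solution
        assert np.abs(vel[:, grid.solid_mask()]).max() == 0.0

    def test_grid_convergence_second_order_trend(self):
        errs = []
        for dx in (12.0, 6.0):
            grid = small_channel(dx=dx)
            _, vel = solve_flow(grid, None, 200.0)
            R = grid.spec.inlet_diameter * 1e3 / 2.0
            u_th = 200.0 * R / 2.0
            errs.append(abs(vel[0][grid.nx // 2].max() - u_th) / u_th)
        assert errs[1] < errs[0]


class TestShearField:
    def test_uniform_flow_has_zero_shear(self):
        # wall-free (fully periodic-like) domain: no gradients anywhere
        grid = small_channel()
        grid.flags[:] = 0  # every node fluid
        vel = np.full((2,) + grid.shape, 1234.0)
        gamma = wall_shear(vel, grid)
        assert np.abs(gamma[1:-1, 1:-1]).max() == 0.0

    def test_matches_finite_difference_oracle_in_interior(self,
                                                          channel_solution):
        grid, _, vel = channel_solution
        gamma = wall_shear(vel, grid)
        # independent central-difference oracle on the velocity field
        dudy = np.gradient(vel[0], grid.spacing, axis=1)
        dvdx = np.gradient(vel[1], grid.spacing, axis=0)
        oracle = np.abs(dudy + dvdx)  # 2 * S_xy for near-unidirectional flow
        lum = grid.lumen_mask()
        interior = lum & np.roll(lum, 1, 1) & np.roll(lum, -1, 1)
        interior[(0, -1), :] = False
        sel = interior & (oracle > 20.0)
        assert np.allclose(gamma[sel], oracle[sel], rtol=0.02)


@pytest.fixture(scope="module")
def stenosis_solution():
    spec = DomainSpec(shape="stenosis", length=1.0, inlet_diameter=0.12,
                      constriction_fraction=0.75, constriction_length=0.5,
                      lattice_spacing=6.0, dimensionality=2)
    grid = build_domain(spec)
    state, vel = solve_flow(grid, None, 1000.0,
                            params=FlowParams(tau_lb=0.65))
    return grid, state, vel


class TestStenosis:
    def test_inlet_wall_shear(self, stenosis_solution):
        grid, _, vel = stenosis_solution
        gamma = wall_shear(vel, grid)
        col = gamma[10][grid.lumen_mask()[10]]  # straight segment
        assert col[0] == pytest.approx(1000.0, rel=0.05)

    def test_apex_velocity_from_continuity(self, stenosis_solution):
        grid, _, vel = stenosis_solution
        lum = grid.lumen_mask()
        apex = grid.nx // 2
        ratio = (vel[0][apex][lum[apex]].mean()
                 / vel[0][2][lum[2]].mean())
        # center-plane gap halves at 75% area reduction -> ~2x mean speed
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_apex_shear_in_vwf_window(self, stenosis_solution):
        grid, _, vel = stenosis_solution
        gamma = wall_shear(vel, grid)
        apex = grid.nx // 2
        assert 3000.0 < gamma[apex][grid.lumen_mask()[apex]].max() < 8000.0

    def test_mass_flux_balance(self, stenosis_solution):
        grid, state, vel = stenosis_solution
        flux = mass_flux_per_column(grid, state, vel)
        assert flux[-2] == pytest.approx(flux[1], rel=0.01)


class TestOcclusion:
    def test_warm_start_matches_cold_start(self):
        grid = small_channel()
        occ = np.zeros(grid.shape, dtype=bool)
        occ[grid.nx // 2, 1:4] = True
        state_empty, _ = solve_flow(grid, None, 200.0)
        warm_state = update_noslip(state_empty, occ, grid)
        _, v_warm = solve_flow(grid, occ, 200.0, state=warm_state)
        _, v_cold = solve_flow(grid, occ, 200.0)
        rel = (np.linalg.norm(v_warm - v_cold)
               / np.linalg.norm(v_cold))
        assert rel < 1e-4

    def test_update_noslip_identity_when_unchanged(self):
        grid = small_channel()
        state, _ = solve_flow(grid, None, 200.0)
        assert update_noslip(state, np.zeros(grid.shape, bool), grid) is state

    def test_growing_occlusion_reduces_outlet_flux(self):
        grid = small_channel()
        fluxes = []
        state = None
        for frac in (0, 3, 5, 7):
            occ = np.zeros(grid.shape, dtype=bool)
            occ[grid.nx // 2, 1:1 + frac] = True
            state, vel = solve_flow(grid, occ, 200.0, state=state)
            flux = mass_flux_per_column(grid, state, vel, occ)
            fluxes.append(flux[1])
        assert all(b <= a * 1.01 for a, b in zip(fluxes, fluxes[1:]))

    def test_full_occlusion_gives_zero_flux(self):
        grid = small_channel()
        occ = np.zeros(grid.shape, dtype=bool)
        occ[grid.nx // 2] = True  # wall-to-wall plug
        _, vel = solve_flow(grid, occ, 200.0)
        lum = grid.lumen_mask() & ~occ
        assert abs(vel[0][-1][lum[-1]].sum()) < 1e-9


class TestThreeD:
    def test_coarse_pipe_poiseuille(self):
        spec = DomainSpec(shape="cylinder", length=0.12, inlet_diameter=0.12,
                          collagen_patch_length=0.0, lattice_spacing=12.0,
                          dimensionality=3)
        grid = build_domain(spec)
        state, vel = solve_flow(grid, None, 200.0)
        # coarse voxelized pipe: centerline within 10%, flux conserved
        assert vel[0][grid.nx // 2].max() == pytest.approx(6000.0, rel=0.10)
        flux = mass_flux_per_column(grid, state, vel)
        assert flux[-2] == pytest.approx(flux[1], rel=0.01)


def test_invalid_relaxation_time_rejected():
    with pytest.raises(ConfigurationError):
        FlowParams(tau_lb=0.5)


def test_negative_inlet_shear_rejected():
    with pytest.raises(ConfigurationError):
        solve_flow(small_channel(), None, -5.0)
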