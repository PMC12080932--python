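"""Convective-diffusive transport of soluble agonists (ADP, TXA2).

The concentration fields live on the same lattice as the flow solution
and are advanced by an explicit, conservative finite-volume scheme:
first-order upwind advection plus central diffusion, flux form on cell
faces. Boundedness (and hence positivity) holds under the usual CFL
restriction, which :meth:`TransportSolver.stable_dt` computes.

Boundary conditions: zero concentration at the inlet (the inlet face is
advective-only), convective outflow at the outlet, no flux through
vessel walls. Bound platelets form a porous aggregate: platelet nodes
remain part of the transport domain with zero local velocity, so
intra-clot transport is diffusion dominated and granule release from a
buried platelet accumulates inside the deposit.

Species are tracked in μM, diffusivities in μm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import INLET, OUTLET, LatticeGrid

__all__ = [
    "SPECIES",
    "TransportParams",
    "ConcentrationField",
    "SourceField",
    "TransportSolver",
    "release_sources",
]

SPECIES = ("ADP", "TXA2")

# 2.4e-6 / 2.1e-6 cm²/s in μm²/s: small-molecule plasma diffusivities
D_ADP_UM2_S = 240.0
D_TXA2_UM2_S = 210.0


@dataclass
class TransportParams:
    """Release and transport constants (all config-exposed).

    ``q_adp_total`` is the dense-granule ADP content of one platelet,
    expressed as the concentration (μM) it would produce if released
    into a single lattice-cell volume; released with first-order rate
    ``k_rel`` once activation crosses the release threshold. TXA2 is
    synthesized at the constant rate ``q_txa2`` (μM/s, same per-cell
    convention) while the platelet stays bound and activated.
    """

    D: tuple = (D_ADP_UM2_S, D_TXA2_UM2_S)  # μm²/s per species
    # dense-granule content sized so the intra-clot ADP bolus saturates
    # the P2Y12 axis across the deposit shortly after release
    q_adp_total: float = 1500.0  # μM (per cell volume)
    k_rel: float = 0.1           # s⁻¹
    q_txa2: float = 0.15         # μM/s
    cfl: float = 0.9


@dataclass
class ConcentrationField:
    """Per-species nodal concentrations, μM; shape (nspecies,) + grid shape."""

    c: np.ndarray
    grid: LatticeGrid

    @classmethod
    def zeros(cls, grid: LatticeGrid, nspecies: int = len(SPECIES)):
        return cls(c=np.zeros((nspecies,) + grid.shape), grid=grid)

    def species(self, name: str) -> np.ndarray:
        return self.c[SPECIES.index(name)]

    def total_mass(self) -> np.ndarray:
        """Per-species mass in μM·μm^dim."""
        v = self.grid.spacing ** self.grid.dim
        return self.c.reshape(self.c.shape[0], -1).sum(axis=1) * v


@dataclass
class SourceField:
    """Per-species nodal release rates (μM/s) with per-node provenance."""

    s: np.ndarray
    provenance: dict = field(default_factory=dict)  # flat node -> platelet id

    @classmethod
    def zeros(cls, grid: LatticeGrid, nspecies: int = len(SPECIES)):
        return cls(s=np.zeros((nspecies,) + grid.shape))


@njit(cache=True, fastmath=True)
def _cdr_substeps(c, u, src, nbr_ax, open_flat, inlet_flat, outlet_flat,
                  D, dx, dt, nsub, vol):
    """Advance ``nsub`` explicit upwind/diffusion steps.

    Returns (source_mass, outflux_mass) accumulated over the substeps in
    μM·μm^dim units.
    """
    ns, nn = c.shape
    d2 = nbr_ax.shape[1]
    dax = d2 // 2
    delta = np.zeros((ns, nn))
    src_mass = 0.0
    out_mass = 0.0
    for _ in range(nsub):
        for s in range(ns):
            for i in range(nn):
                delta[s, i] = 0.0
        for i in range(nn):
            if not open_flat[i]:
                continue
            for a in range(dax):
                j = nbr_ax[i, 2 * a]  # +axis neighbor
                if j >= 0 and open_flat[j]:
                    uf = 0.5 * (u[a, i] + u[a, j])
                    for s in range(ns):
                        cup = c[s, i] if uf >= 0.0 else c[s, j]
                        flux = uf * cup
                        # inlet face: advective only (upstream c is zero
                        # anyway); interior faces add central diffusion
                        if not (inlet_flat[i] or inlet_flat[j]):
                            flux -= D[s] * (c[s, j] - c[s, i]) / dx
                        delta[s, i] -= flux / dx
                        delta[s, j] += flux / dx
                elif outlet_flat[i] and j < 0:
                    # convective outflow through the open end
                    if u[a, i] > 0.0:
                        for s in range(ns):
                            flux = u[a, i] * c[s, i]
                            delta[s, i] -= flux / dx
                            out_mass += flux / dx * dt * vol
        for i in range(nn):
            if not open_flat[i] or inlet_flat[i]:
                continue
            for s in range(ns):
                c[s, i] += dt * (delta[s, i] + src[s, i])
                src_mass += src[s, i] * dt * vol
    return src_mass, out_mass


def axis_neighbor_table(shape: tuple) -> np.ndarray:
    """Flat neighbor indices ordered [+x, -x, +y, -y, (+z, -z)]; -1 outside."""
    dim = len(shape)
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    nbr = np.empty((idx.size, 2 * dim), dtype=np.int64)
    col = 0
    for a in range(dim):
        for s in (1, -1):
            shifted = np.roll(idx, -s, axis=a)
            ok = np.ones(shape, dtype=bool)
            sel = [slice(None)] * dim
            sel[a] = -1 if s > 0 else 0
            ok[tuple(sel)] = False
            nbr[:, col] = np.where(ok.ravel(), shifted.ravel(), -1)
            col += 1
    return nbr


class CFLError(ValueError):
    """Time step violates the explicit scheme's stability bound."""


class TransportSolver:
    """Finite-volume CDR solver bound to a lattice grid."""

    def __init__(self, grid: LatticeGrid, params: TransportParams | None = None):
        self.grid = grid
        self.params = params or TransportParams()
        self.nbr_ax = axis_neighbor_table(grid.shape)
        flags = grid.flags.ravel()
        self._lumen = grid.lumen_mask().ravel()
        self._inlet = flags == INLET
        self._outlet = flags == OUTLET
        self.source_mass = 0.0
        self.outflux_mass = 0.0

    def open_mask(self, occupancy: np.ndarray | None = None) -> np.ndarray:
        """Transport domain: lumen nodes; platelet nodes stay open (porous)."""
        return self._lumen

    def stable_dt(self, vel: np.ndarray) -> float:
        """Largest admissible explicit step for the current velocity field."""
        dx = self.grid.spacing
        dim = self.grid.dim
        speed = np.abs(vel.reshape(dim, -1)).sum(axis=0)  # Σ|u_a| per node
        Dmax = max(self.params.D)
        denom = speed / dx + 2.0 * dim * Dmax / dx**2
        return self.params.cfl / denom.max()

    def step(self, conc: ConcentrationField, vel: np.ndarray,
             src: SourceField, dt: float) -> ConcentrationField:
        """One explicit step of size ``dt`` (raises CFLError if too large)."""
        admissible = self.stable_dt(vel) / self.params.cfl
        if dt > admissible * (1.0 + 1e-12):
            raise CFLError(
                f"dt={dt:g} s violates the stability bound; "
                f"admissible dt <= {admissible:g} s")
        self._run(conc, vel, src, dt, 1)
        return conc

    def advance(self, conc: ConcentrationField, vel: np.ndarray,
                src: SourceField, horizon: float) -> ConcentrationField:
        """Advance by ``horizon`` seconds using stable substeps."""
        if horizon <= 0:
            return conc
        dt_max = self.stable_dt(vel)
        nsub = max(1, int(np.ceil(horizon / dt_max)))
        self._run(conc, vel, src, horizon / nsub, nsub)
        return conc

    def _run(self, conc, vel, src, dt, nsub):
        dim = self.grid.dim
        sm, om = _cdr_substeps(
            conc.c.reshape(conc.c.shape[0], -1),
            np.ascontiguousarray(vel.reshape(dim, -1)),
            src.s.reshape(src.s.shape[0], -1),
            self.nbr_ax, self._lumen, self._inlet, self._outlet,
            np.asarray(self.params.D, dtype=np.float64),
            self.grid.spacing, dt, nsub, self.grid.spacing ** dim)
        self.source_mass += sm
        self.outflux_mass += om


def release_sources(platelets, params: TransportParams, t: float,
                    grid: LatticeGrid) -> SourceField:
    """Granule-release source field at time ``t``.

    ``platelets`` is an iterable of objects with attributes ``node``
    (tuple index), ``bound`` (bool), ``released`` (bool) and
    ``t_release`` (crossing time, s). A platelet past the activation
    threshold releases its ADP content with first-order kinetics
    (``q_adp_total * k_rel * exp(-k_rel (t - t0))``) and synthesizes
    TXA2 at a constant rate while it remains bound.
    """
    src = SourceField.zeros(grid)
    i_adp = SPECIES.index("ADP")
    i_txa = SPECIES.index("TXA2")
    for p in platelets:
        if not (p.released and p.bound):
            continue
        dt_rel = t - p.t_release
        if dt_rel < 0:
            continue
        node = tuple(p.node)
        src.s[(i_adp,) + node] += (
            params.q_adp_total * params.k_rel * np.exp(-params.k_rel * dt_rel))
        src.s[(i_txa,) + node] += params.q_txa2
        src.provenance[node] = getattr(p, "id", None)
    return src
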