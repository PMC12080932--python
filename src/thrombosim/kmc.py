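"""Lattice kinetic Monte Carlo of platelet motion, adhesion and detachment.

Platelets occupy single lattice nodes and evolve by a rejection-free
KMC: a catalog of all possible events (directional hops, attachment,
detachment) with absolute rates is kept current, events are selected
with probability proportional to their rates, and the clock advances by
exponential waiting times ``dt = -ln(u)/R_tot``.

Rates
-----
* motion: ``D_p/dx^2`` per direction plus upwind convection
  ``max(0, u·e)/dx`` — an advected random walk matching platelet
  dispersion in flowing blood (the RBC-augmented effective diffusivity
  absorbs margination physics that single-platelet Brownian motion would
  miss);
* attachment (mobile platelet adjacent to collagen or to a bound
  platelet): ``k_att0 * F * W(gamma)``, with a larger prefactor for
  collagen (GPVI/GPIb capture) and the smooth vWF enhancement
  ``W(gamma) = 1 + (W_max - 1) * sigmoid((gamma - gamma_vwf)/s_vwf)``
  switching on across the 3000-8000 1/s pathological-shear window;
* detachment (slip bond): ``k_det0 * (1/F) * exp(gamma/gamma_c)``.

This module holds the platelet-level operations and a transparent
reference :class:`RateDatabase`; the production event loop used by the
orchestrator lives in :mod:`thrombosim.engine` and computes identical
rates from precomputed node tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .geometry import LatticeGrid
from .signaling import ActivationState, CalciumTrace

__all__ = [
    "KMCParams",
    "Platelet",
    "motion_rates",
    "vwf_factor",
    "bond_rates",
    "RateDatabase",
    "EventRecord",
    "select_execute",
    "inlet_insertion_profile",
    "insert_inlet_platelets",
]

C_BULK_PER_UL = 1.5e5  # platelets per μL of whole blood


@dataclass
class KMCParams:
    """Platelet transport, bonding and insertion constants.

    Defaults are calibrated so that (a) a quiescent collagen surface at
    venous shear (200 1/s) acquires a platelet monolayer within about a
    minute, and (b) detachment of a fully activated platelet is
    negligible at shear rates up to 1000 1/s.
    """

    D_p: float = 25.0            # μm²/s (2.5e-7 cm²/s effective diffusivity)
    # collagen capture is kept slow enough that attachment probability per
    # wall contact stays well below one: capture is then proportional to
    # the vWF factor W(gamma) rather than saturating in stagnant corners
    k_att_col: float = 1.0e2     # s⁻¹, collagen capture prefactor
    # platelet-platelet recruitment strong enough that growth on an
    # activated deposit is supply-limited at venous shear (first-contact,
    # hence upstream-weighted) while staying vWF-limited at arterial
    # near-wall speeds
    k_att_pp: float = 2.0e2      # s⁻¹, platelet-platelet prefactor
    k_det_col: float = 1.0e-5    # s⁻¹, collagen-bond detach prefactor
    # passive (F = alpha_min) platelet-platelet tethers are transient
    # (sub-second at venous shear) so unactivated platelets cannot pave
    # the wall or pile up in stagnation corners; activated bonds are
    # ~1e4x more persistent (F enters attachment and detachment)
    k_det_pp: float = 3.0e-2     # s⁻¹, platelet-bond detach prefactor
    # slip-bond e-folding scale: chosen so passive bonds at the stenotic
    # apex (~4000 1/s) survive long enough for contact activation, while
    # detachment still grows steeply into the pathological-shear range
    gamma_c: float = 3000.0      # s⁻¹, slip-bond shear scale
    # the vWF enhancement must outgrow the ~1/gamma near-wall residence
    # time for capture to concentrate at pathological shear, hence the
    # large plateau and a midpoint at the lower end of the switch window
    w_max: float = 150.0         # vWF enhancement plateau
    gamma_vwf: float = 4000.0    # s⁻¹, vWF switch midpoint (3000-8000 window)
    s_vwf: float = 500.0         # s⁻¹, vWF switch width
    c_bulk: float = C_BULK_PER_UL
    margination_excess: float = 4.0   # near-wall concentration factor E
    margination_delta: float = 6.0    # μm boundary-layer thickness
    insertion_band: float | None = None  # simulate only insertions within
    # this distance (μm) of a wall; None = all (statistics unchanged,
    # pass-through platelets that can never reach the wall are skipped)


@dataclass
class Platelet:
    """One platelet: lattice position, bond state and signaling state."""

    id: int
    node: tuple
    mobile: bool = True
    bound_neighbors: set = field(default_factory=set)  # node tuples / pids
    trace: CalciumTrace | None = None
    activation: ActivationState | None = None
    t_entry: float = 0.0

    @property
    def bound(self) -> bool:
        return not self.mobile


def motion_rates(u: np.ndarray, D_p: float, dx: float,
                 blocked: np.ndarray | None = None) -> np.ndarray:
    """Directional hop rates, ordered [+x, -x, +y, -y, (+z, -z)] (s⁻¹).

    Symmetric diffusion ``D_p/dx²`` plus upwind convection
    ``max(0, u·e)/dx``; directions into walls or occupied nodes
    (``blocked``) get rate zero.
    """
    u = np.asarray(u, dtype=float)
    d = len(u)
    rates = np.empty(2 * d)
    base = D_p / dx ** 2
    for a in range(d):
        rates[2 * a] = base + max(0.0, u[a]) / dx
        rates[2 * a + 1] = base + max(0.0, -u[a]) / dx
    if blocked is not None:
        rates[np.asarray(blocked, dtype=bool)] = 0.0
    return rates


def vwf_factor(gamma, params: KMCParams):
    """Smooth vWF adhesion enhancement W(gamma) >= 1, monotone in gamma.

    The sigmoid is rescaled so that W(0) = 1 exactly (no enhancement in
    stasis) and W -> w_max at saturating shear.
    """
    s0 = expit(-params.gamma_vwf / params.s_vwf)
    s = expit((np.asarray(gamma, dtype=float) - params.gamma_vwf)
              / params.s_vwf)
    return 1.0 + (params.w_max - 1.0) * (s - s0) / (1.0 - s0)


def bond_rates(F: float, gamma: float, params: KMCParams,
               collagen: bool = False,
               alpha_bounds: tuple = (0.01, 1.0)) -> tuple:
    """(attach, detach) rates for adhesiveness ``F`` at shear ``gamma``.

    ``F`` must lie within the Hill bounds; ``collagen`` selects the
    collagen-bond prefactors.
    """
    lo, hi = alpha_bounds
    if not lo - 1e-12 <= F <= hi + 1e-12:
        raise ValueError(f"adhesiveness F={F} outside [{lo}, {hi}]")
    if gamma < 0:
        raise ValueError("shear rate must be non-negative")
    k_att = params.k_att_col if collagen else params.k_att_pp
    k_det = params.k_det_col if collagen else params.k_det_pp
    attach = k_att * F * float(vwf_factor(gamma, params))
    detach = k_det * (1.0 / F) * float(np.exp(gamma / params.gamma_c))
    return attach, detach


@dataclass
class EventRecord:
    kind: str          # "hop+x", "attach", "detach", ...
    pid: int
    rate: float
    time: float | None = None


class RateDatabase:
    """Transparent event catalog with rate-proportional selection.

    Events are registered per platelet as ``(kind, rate)`` pairs;
    selection draws an event with probability ``rate / R_tot`` using a
    cumulative-sum search. Stale entries are replaced wholesale via
    :meth:`set_events` whenever a platelet's neighborhood changes, which
    keeps updates local.
    """

    def __init__(self):
        self._events: dict[int, list] = {}
        self._dirty = True
        self._keys = None
        self._cum = None

    def set_events(self, pid: int, events: list) -> None:
        """Replace platelet ``pid``'s catalog entries (list of (kind, rate))."""
        events = [(k, r) for k, r in events if r > 0.0]
        if events:
            self._events[pid] = events
        else:
            self._events.pop(pid, None)
        self._dirty = True

    def remove(self, pid: int) -> None:
        self.set_events(pid, [])

    def _rebuild(self):
        keys, rates = [], []
        for pid, evs in self._events.items():
            for kind, r in evs:
                keys.append((pid, kind))
                rates.append(r)
        self._keys = keys
        self._cum = np.cumsum(rates) if rates else np.empty(0)
        self._dirty = False

    @property
    def total_rate(self) -> float:
        if self._dirty:
            self._rebuild()
        return float(self._cum[-1]) if len(self._cum) else 0.0

    def rates(self) -> dict:
        return {pid: list(evs) for pid, evs in self._events.items()}


class QuiescentState(Exception):
    """No executable events: advance the clock to the next insertion."""


def select_execute(db: RateDatabase, rng: np.random.Generator
                   ) -> tuple[EventRecord, float]:
    """Draw the next event and its exponential waiting time.

    Returns ``(EventRecord, dt)``; the caller applies the event to the
    system and refreshes the affected platelets' entries. Raises
    :class:`QuiescentState` when the catalog is empty.
    """
    R = db.total_rate
    if R <= 0.0:
        raise QuiescentState
    target = rng.random() * R
    i = int(np.searchsorted(db._cum, target, side="right"))
    i = min(i, len(db._keys) - 1)
    pid, kind = db._keys[i]
    rate = db._cum[i] - (db._cum[i - 1] if i else 0.0)
    dt = -np.log(max(rng.random(), 1e-300)) / R
    return EventRecord(kind=kind, pid=pid, rate=float(rate)), float(dt)


# --- inlet insertion -------------------------------------------------------

def inlet_insertion_profile(grid: LatticeGrid, vel: np.ndarray,
                            params: KMCParams):
    """Flux-weighted insertion statistics at the inlet face.

    The near-wall platelet excess (margination imposed by unresolved red
    cells) follows ``phi(r) = 1 + (E - 1) exp(-(R - r)/delta)``,
    normalized so that the mixing-cup (flux-weighted) concentration
    equals the configured bulk platelet count ``c_bulk``.

    Returns ``(nodes, weights, rate, Q)``: inlet lumen node indices
    (tuples), per-node sampling weights (insertions/s), the total
    insertion rate (1/s) over the simulated band, and the volumetric
    flow rate Q (μm³/s; 2D domains count a slab one lattice spacing
    deep).
    """
    lumen0 = grid.lumen_mask()[0]
    ux = vel[0][0]                      # axial velocity on the inlet face
    r = grid.radial_distance()[0]
    R = grid.spec.inlet_diameter * 1e3 / 2.0
    dA = grid.spacing ** 2              # per-node face area (slab depth dx in 2D)
    u_nodes = np.clip(ux[lumen0], 0.0, None)
    r_nodes = r[lumen0]
    E, delta = params.margination_excess, params.margination_delta
    phi = 1.0 + (E - 1.0) * np.exp(-(R - r_nodes) / delta)
    Q = float((u_nodes * dA).sum())
    c_bulk_um3 = params.c_bulk * 1e-9   # μL⁻¹ -> μm⁻³
    # normalize so the flux-weighted mean concentration is exactly c_bulk
    c_ref = c_bulk_um3 * Q / float((phi * u_nodes * dA).sum())
    weights = c_ref * phi * u_nodes * dA   # insertions/s per node
    if params.insertion_band is not None:
        # band measured from the effective (voxelized) wall position so
        # it keeps selecting the outermost rows when the nominal radius
        # is not commensurate with the lattice
        r_wall = r_nodes.max() + grid.spacing / 2.0
        weights = np.where(r_wall - r_nodes <= params.insertion_band,
                           weights, 0.0)
    nodes = [tuple(ix) for ix in np.argwhere(lumen0)]
    return nodes, weights, float(weights.sum()), Q


def insert_inlet_platelets(grid: LatticeGrid, vel: np.ndarray,
                           dt: float, rng: np.random.Generator,
                           params: KMCParams) -> list:
    """Sample the Poisson number of inlet insertions over a window ``dt``.

    Returns a list of full node indices (x = 0 column) sampled from the
    flux-weighted near-wall-excess density.
    """
    nodes, weights, rate, _ = inlet_insertion_profile(grid, vel, params)
    if dt <= 0 or rate <= 0:
        return []
    n = rng.poisson(rate * dt)
    if n == 0:
        return []
    p = weights / weights.sum()
    picks = rng.choice(len(nodes), size=n, p=p)
    return [(0,) + nodes[i] for i in picks]
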