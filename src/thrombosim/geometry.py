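"""Voxelized vessel domains and lattice conventions.

Two geometries are supported: a straight cylindrical vessel (venous case)
and an axisymmetric stenotic vessel with a smooth cosine constriction
(arterial case). The same cubic lattice is shared by the flow, transport
and platelet modules; this module owns its conventions:

* flow is along +x; node indices are 0-based;
* axial node columns are node-centered at ``x_i = i * spacing`` with
  ``nx = floor(L / spacing) + 1`` columns covering ``[0, L]``;
* cross-sectional coordinates are staggered by half a spacing so that the
  nominal vessel wall falls exactly on the half-link between the last
  fluid node and the first solid node (the effective location of a
  full-way bounce-back wall);
* in 2D the domain is the axial-radial center plane of the 3D vessel,
  i.e. a plane channel of height equal to the local diameter.

Node flags: FLUID, WALL, INLET, OUTLET, COLLAGEN. Collagen nodes are wall
nodes (a reactive subset); inlet/outlet nodes are lumen nodes on the
x = 0 and x = L planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FLUID",
    "WALL",
    "INLET",
    "OUTLET",
    "COLLAGEN",
    "DomainSpec",
    "LatticeGrid",
    "build_cylinder",
    "build_stenosis",
    "build_domain",
    "reactive_surface_mask",
]

FLUID = 0
WALL = 1
INLET = 2
OUTLET = 3
COLLAGEN = 4


class ConfigurationError(ValueError):
    """Raised for inconsistent domain / solver configuration."""


@dataclass(frozen=True)
class DomainSpec:
    """Geometric description of a simulation domain.

    Lengths are millimetres except ``lattice_spacing`` (micrometres).

    Parameters
    ----------
    shape
        ``"cylinder"`` (straight vessel) or ``"stenosis"``.
    length
        Axial extent of the domain, mm.
    inlet_diameter
        Lumen diameter at the inlet, mm.
    constriction_fraction
        Fractional reduction of cross-sectional *area* at the stenosis
        apex (0.75 reduces the flow area by 75%). Stenosis only.
    constriction_length
        Axial extent of the constriction, mm (centered). Stenosis only.
    collagen_patch_length
        Axial extent of the reactive collagen patch, mm. For the
        cylinder the patch is centered axially; for the stenosis the
        collagen covers the constricted region (this field is ignored
        and the constriction length is used).
    collagen_circumference_fraction
        Fraction of the circumference covered by collagen, centered on
        the "bottom" (-y) side. In 2D a fraction < 1 puts the patch on
        the bottom wall only.
    lattice_spacing
        Cubic lattice spacing, micrometres.
    dimensionality
        2 (center plane) or 3.
    """

    shape: Literal["cylinder", "stenosis"]
    length: float = 0.5
    inlet_diameter: float = 0.12
    constriction_fraction: float = 0.75
    constriction_length: float = 0.5
    collagen_patch_length: float = 0.25
    collagen_circumference_fraction: float = 0.5
    lattice_spacing: float = 3.0
    dimensionality: int = 2

    def __post_init__(self) -> None:
        if self.lattice_spacing <= 0:
            raise ConfigurationError("lattice_spacing must be positive")
        if self.dimensionality not in (2, 3):
            raise ConfigurationError("dimensionality must be 2 or 3")
        if self.collagen_patch_length > self.length + 1e-12:
            raise ConfigurationError("collagen patch longer than the domain")
        if self.shape == "stenosis":
            if not 0.0 < self.constriction_fraction < 1.0:
                raise ConfigurationError(
                    "constriction_fraction must lie strictly in (0, 1)"
                )
            if self.constriction_length > self.length + 1e-12:
                raise ConfigurationError("constriction longer than the domain")
        if not 0.0 <= self.collagen_circumference_fraction <= 1.0:
            raise ConfigurationError(
                "collagen_circumference_fraction must lie in [0, 1]"
            )


@dataclass
class LatticeGrid:
    """Voxelized domain: flag array plus lattice metadata.

    ``flags`` has shape ``(nx, ny)`` in 2D or ``(nx, ny, nz)`` in 3D.
    ``spacing`` is in micrometres. Cross-sectional node coordinates (μm,
    relative to the vessel axis) are staggered by half a spacing.
    """

    flags: np.ndarray
    spacing: float
    spec: DomainSpec
    radius_profile: np.ndarray = field(repr=False, default=None)  # μm per column

    # -- basic masks -------------------------------------------------
    @property
    def dim(self) -> int:
        return self.flags.ndim

    @property
    def nx(self) -> int:
        return self.flags.shape[0]

    @property
    def shape(self) -> tuple:
        return self.flags.shape

    def lumen_mask(self) -> np.ndarray:
        """Nodes inside the lumen (fluid plus inlet/outlet layers)."""
        return (self.flags == FLUID) | (self.flags == INLET) | (self.flags == OUTLET)

    def solid_mask(self) -> np.ndarray:
        return (self.flags == WALL) | (self.flags == COLLAGEN)

    def collagen_mask(self) -> np.ndarray:
        return self.flags == COLLAGEN

    # -- coordinates -------------------------------------------------
    def axial_coords(self) -> np.ndarray:
        """x of each node column, μm."""
        return np.arange(self.nx) * self.spacing

    def cross_coords(self) -> tuple[np.ndarray, ...]:
        """Half-staggered transverse coordinates (μm, axis-centered)."""
        out = []
        for n in self.flags.shape[1:]:
            out.append((np.arange(n) - (n - 1) / 2.0) * self.spacing)
        return tuple(out)

    def radial_distance(self) -> np.ndarray:
        """Distance of every node from the vessel axis, μm (cross-section only)."""
        cross = self.cross_coords()
        if self.dim == 2:
            return np.abs(np.broadcast_to(cross[0], self.flags.shape))
        y = cross[0][:, None]
        z = cross[1][None, :]
        r = np.hypot(y, z)
        return np.broadcast_to(r, self.flags.shape)

    def cross_section_area(self, i: int) -> float:
        """Open (lumen) area of column ``i``: μm² in 3D, gap height μm in 2D."""
        lumen = self.lumen_mask()[i]
        if self.dim == 3:
            return float(lumen.sum()) * self.spacing**2
        return float(lumen.sum()) * self.spacing


def _cross_grid(spec: DomainSpec) -> tuple[np.ndarray, ...]:
    """Half-staggered transverse node coordinates covering lumen + 1 wall layer."""
    R = spec.inlet_diameter * 1e3 / 2.0  # μm
    dx = spec.lattice_spacing
    n_half = int(np.floor((R - dx / 2.0) / dx)) + 1  # nodes strictly inside R per side
    n = 2 * (n_half + 1)  # plus one wall layer each side
    coords = (np.arange(n) - (n - 1) / 2.0) * dx
    if spec.dimensionality == 2:
        return (coords,)
    return (coords, coords)


def _radius_profile(spec: DomainSpec, x: np.ndarray) -> np.ndarray:
    """Local lumen radius r(x) in μm."""
    R = spec.inlet_diameter * 1e3 / 2.0
    if spec.shape == "cylinder":
        return np.full_like(x, R, dtype=float)
    L = spec.length * 1e3
    Lc = spec.constriction_length * 1e3
    xc = L / 2.0
    w = np.zeros_like(x, dtype=float)
    inside = np.abs(x - xc) <= Lc / 2.0
    # C1-smooth cosine bump, 1 at the apex, 0 at the constriction edges
    w[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (x[inside] - xc) / Lc))
    return R * np.sqrt(1.0 - spec.constriction_fraction * w)


def _build(spec: DomainSpec) -> LatticeGrid:
    dx = spec.lattice_spacing
    L = spec.length * 1e3
    nx = int(np.floor(L / dx)) + 1
    x = np.arange(nx) * dx
    r_of_x = _radius_profile(spec, x)
    cross = _cross_grid(spec)

    if spec.dimensionality == 2:
        rdist = np.abs(cross[0])[None, :]  # (1, ny)
    else:
        rdist = np.hypot(cross[0][:, None], cross[1][None, :])[None, :, :]

    lumen = rdist < r_of_x.reshape((nx,) + (1,) * (spec.dimensionality - 1))
    flags = np.full(lumen.shape, WALL, dtype=np.int8)
    flags[lumen] = FLUID
    flags[0][lumen[0]] = INLET
    flags[-1][lumen[-1]] = OUTLET

    _flag_collagen(spec, flags, x, rdist, cross)
    return LatticeGrid(flags=flags, spacing=dx, spec=spec,
                       radius_profile=r_of_x)


def _wall_adjacent_to_lumen(flags: np.ndarray) -> np.ndarray:
    """Wall nodes with at least one lumen-side axis neighbor."""
    lumen = (flags == FLUID) | (flags == INLET) | (flags == OUTLET)
    adj = np.zeros_like(lumen)
    for axis in range(flags.ndim):
        for shift in (1, -1):
            adj |= np.roll(lumen, shift, axis=axis)
    # roll wraps around; wrapped contamination only matters if lumen touches
    # the array edge, which the construction precludes transversely and is
    # irrelevant axially (inlet/outlet faces are lumen anyway).
    return adj & (flags == WALL)


def _flag_collagen(spec, flags, x, rdist, cross) -> None:
    if spec.shape == "cylinder":
        patch = spec.collagen_patch_length * 1e3
        xc = spec.length * 1e3 / 2.0
        span = np.abs(x - xc) <= patch / 2.0 + 1e-9
        if patch <= 0:
            return
    else:
        Lc = spec.constriction_length * 1e3
        xc = spec.length * 1e3 / 2.0
        span = np.abs(x - xc) <= Lc / 2.0 + 1e-9

    frac = spec.collagen_circumference_fraction
    if frac <= 0:
        return
    candidate = _wall_adjacent_to_lumen(flags)
    if spec.dimensionality == 2:
        # bottom wall (-y side) unless the full circumference is requested
        side = cross[0] < 0 if frac < 1.0 else np.ones_like(cross[0], dtype=bool)
        sector = np.broadcast_to(side[None, :], flags.shape)
    else:
        y = cross[0][:, None]
        z = cross[1][None, :]
        # angle from the "bottom" (-y) direction
        phi = np.arccos(np.clip(-y / np.maximum(np.hypot(y, z), 1e-12), -1, 1))
        sector = np.broadcast_to((phi <= np.pi * frac + 1e-12)[None], flags.shape)
    axial = span.reshape((len(x),) + (1,) * (spec.dimensionality - 1))
    flags[candidate & sector & np.broadcast_to(axial, flags.shape)] = COLLAGEN


def build_cylinder(spec: DomainSpec) -> LatticeGrid:
    """Voxelize a straight vessel with a centered collagen patch."""
    if spec.shape != "cylinder":
        raise ConfigurationError("spec.shape must be 'cylinder'")
    return _build(spec)


def build_stenosis(spec: DomainSpec) -> LatticeGrid:
    """Voxelize a stenotic vessel (smooth cosine constriction).

    The minimal cross-sectional flow area equals
    ``(1 - constriction_fraction)`` times the inlet area (up to voxel
    discretization); the collagen mask covers the constricted wall over
    the configured circumferential fraction.
    """
    if spec.shape != "stenosis":
        raise ConfigurationError("spec.shape must be 'stenosis'")
    return _build(spec)


def build_domain(spec: DomainSpec) -> LatticeGrid:
    """Dispatch on ``spec.shape``."""
    if spec.shape == "cylinder":
        return build_cylinder(spec)
    return build_stenosis(spec)


def reactive_surface_mask(grid: LatticeGrid) -> np.ndarray:
    """Indices of collagen nodes, lexicographically ordered, shape (n, dim)."""
    return np.argwhere(grid.flags == COLLAGEN)
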