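"""Mother-machine geometry and steady microchannel flow fields.

The device is modelled as a periodic unit cell: a main channel (height
``H`` = 25 um in z, width ``W`` = 100 um in y, periodic along the flow axis
x) with dead-end side channels of 1 x 1 um cross-section and 25 um length
opening into the y = 0 wall near the floor, like the bacteria-hosting
growth channels of a mother machine.

For steady, pressure-driven, unidirectional creeping flow the axial Stokes
equation reduces to a Poisson problem for u_x(y, z) over the rectangular
cross-section with no-slip walls.  Two independent solvers are provided:

- ``"series"``: the classical rectangular-duct Fourier series (exact).
- ``"poisson"``: a sparse finite-difference solve of the same equation.

Both are rescaled so the integrated flux through the cross-section matches
the requested volumetric flow rate exactly; flow inside the dead-end side
channels is taken as zero (their interiors carry no net flux and their
openings are ~1 um wide in a 25-um-deep main channel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["Geometry", "FlowField", "solve_flow", "UL_PER_H_TO_UM3_PER_S"]

#: 1 ul = 1e9 um^3
UL_PER_H_TO_UM3_PER_S = 1.0e9 / 3600.0


@dataclass(frozen=True)
class Geometry:
    """Periodic mother-machine unit cell (lengths in micrometres).

    The main channel occupies 0 <= y <= main_width, 0 <= z <= main_height
    and is periodic in x with period ``unit_cell_length``.  ``n_side``
    dead-end side channels of cross-section side_width x side_height and
    length ``side_length`` open into the y = 0 wall (footprint at
    0 <= z <= side_height, x centred on evenly spaced positions) and
    extend to y = -side_length.
    """

    main_height: float = 25.0
    main_width: float = 100.0
    side_width: float = 1.0
    side_height: float = 1.0
    side_length: float = 25.0
    n_side: int = 2
    unit_cell_length: float = 25.0
    lattice_spacing: float = 0.125

    def __post_init__(self) -> None:
        dims = {
            "main_height": self.main_height,
            "main_width": self.main_width,
            "side_width": self.side_width,
            "side_height": self.side_height,
            "side_length": self.side_length,
            "unit_cell_length": self.unit_cell_length,
        }
        for name, value in dims.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
            ratio = value / self.lattice_spacing
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"{name}={value} is not an integer multiple of "
                    f"lattice_spacing={self.lattice_spacing}"
                )
        if self.n_side < 1:
            raise ValueError("n_side must be >= 1")
        if self.n_side * self.side_width > self.unit_cell_length:
            raise ValueError("side channels do not fit in the unit cell")
        if self.side_height > self.main_height:
            raise ValueError("side_height exceeds main channel height")

    @property
    def side_centers_x(self) -> np.ndarray:
        """x-coordinates of the side-channel centres (evenly pitched)."""
        pitch = self.unit_cell_length / self.n_side
        return (np.arange(self.n_side) + 0.5) * pitch

    @property
    def cross_section_area(self) -> float:
        """Main-channel cross-section area, um^2."""
        return self.main_width * self.main_height

    @property
    def fluid_volume(self) -> float:
        """Total fluid volume of the unit cell (main + side channels), um^3."""
        main = self.unit_cell_length * self.main_width * self.main_height
        side = self.n_side * self.side_width * self.side_height * self.side_length
        return main + side


def _cosh_ratio(x: np.ndarray, big: float) -> np.ndarray:
    """cosh(x)/cosh(big) computed without overflow (x >= 0, big >= 0)."""
    return np.exp(x - big) * (1.0 + np.exp(-2.0 * x)) / (1.0 + np.exp(-2.0 * big))


def _duct_series_profile(y: np.ndarray, z: np.ndarray, W: float, H: float,
                         n_terms: int = 60) -> np.ndarray:
    """Unnormalised rectangular-duct axial velocity on a (y, z) grid.

    Fourier series with the cosine expansion along the short (z) side;
    exact no-slip on all four walls in the truncation limit.
    """
    yy, zz = np.meshgrid(y, z, indexing="ij")
    eta = zz - H / 2.0
    xi = np.abs(yy - W / 2.0)
    u = np.zeros_like(yy, dtype=float)
    for m in range(n_terms):
        i = 2 * m + 1
        sign = -1.0 if (m % 2) else 1.0
        big = i * math.pi * W / (2.0 * H)
        ratio = _cosh_ratio(i * math.pi * xi / H, big)
        u += (sign / i**3) * (1.0 - ratio) * np.cos(i * math.pi * eta / H)
    return u


def _poisson_profile(W: float, H: float, spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Finite-difference solution of -lap(u) = 1 with u = 0 on the walls."""
    ny = int(round(W / spacing))
    nz = int(round(H / spacing))
    y = np.linspace(0.0, W, ny + 1)
    z = np.linspace(0.0, H, nz + 1)
    niy, niz = ny - 1, nz - 1  # interior nodes
    n = niy * niz
    main = sp.eye(n) * (4.0 / spacing**2)
    offs = []
    # neighbours in z (fast axis)
    dz = np.ones(n - 1)
    dz[niz - 1 :: niz] = 0.0  # no coupling across y-rows
    offs.append(sp.diags(dz, 1))
    offs.append(sp.diags(dz, -1))
    # neighbours in y
    offs.append(sp.diags(np.ones(n - niz), niz))
    offs.append(sp.diags(np.ones(n - niz), -niz))
    A = main - sum(offs) * (1.0 / spacing**2)
    b = np.ones(n)
    u_int = spla.spsolve(A.tocsr(), b)
    u = np.zeros((ny + 1, nz + 1))
    u[1:-1, 1:-1] = u_int.reshape(niy, niz)
    return y, z, u


@dataclass
class FlowField:
    """Steady axial flow u_x(y, z) in the main channel.

    ``ux`` holds node values on a regular (y, z) grid with spacing
    ``spacing``; velocity is zero inside the side channels and outside the
    fluid.  ``flow_rate`` is the volumetric rate in ul/h that the profile
    integrates to.
    """

    geometry: Geometry
    ux: np.ndarray
    spacing: float
    flow_rate: float
    method: str = "series"
    y: np.ndarray = field(repr=False, default=None)
    z: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.y is None:
            self.y = np.arange(self.ux.shape[0]) * self.spacing
        if self.z is None:
            self.z = np.arange(self.ux.shape[1]) * self.spacing

    def flux(self) -> float:
        """Integrated flux through the main cross-section, um^3/s."""
        return float(np.trapezoid(np.trapezoid(self.ux, self.z, axis=1), self.y))

    @property
    def flow_rate_um3_s(self) -> float:
        return self.flow_rate * UL_PER_H_TO_UM3_PER_S

    @property
    def mean_speed(self) -> float:
        """Cross-section-averaged axial speed, um/s."""
        return self.flow_rate_um3_s / self.geometry.cross_section_area

    def max_speed(self) -> float:
        return float(self.ux.max()) if self.ux.size else 0.0

    def velocity_at(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of u_x at main-channel points (um/s)."""
        g = self.geometry
        yc = np.clip(np.asarray(y, dtype=float), 0.0, g.main_width)
        zc = np.clip(np.asarray(z, dtype=float), 0.0, g.main_height)
        fy = yc / self.spacing
        fz = zc / self.spacing
        iy = np.minimum(fy.astype(int), self.ux.shape[0] - 2)
        iz = np.minimum(fz.astype(int), self.ux.shape[1] - 2)
        ty = fy - iy
        tz = fz - iz
        u = (
            self.ux[iy, iz] * (1 - ty) * (1 - tz)
            + self.ux[iy + 1, iz] * ty * (1 - tz)
            + self.ux[iy, iz + 1] * (1 - ty) * tz
            + self.ux[iy + 1, iz + 1] * ty * tz
        )
        return u


def solve_flow(geometry: Geometry, flow_rate: float, method: str = "series",
               spacing: float | None = None, n_terms: int = 60) -> FlowField:
    """Solve the steady axial flow for a target volumetric rate.

    Parameters
    ----------
    geometry : Geometry
    flow_rate : volumetric flow through the main channel, ul/h.
    method : "series" (rectangular-duct Fourier series, default) or
        "poisson" (sparse finite-difference solve of the same equation).
    spacing : grid spacing for the stored profile, um.  Defaults to
        2x the geometry lattice spacing for "series" and 0.5 um for
        "poisson" (the linear solve scales with the node count).

    Returns a :class:`FlowField` whose integrated flux equals ``flow_rate``
    exactly (the profile is rescaled after solving).
    """
    if flow_rate < 0:
        raise ValueError("flow_rate must be >= 0")
    W, H = geometry.main_width, geometry.main_height
    if method == "series":
        h = spacing if spacing is not None else 2.0 * geometry.lattice_spacing
        y = np.arange(0.0, W + h / 2, h)
        z = np.arange(0.0, H + h / 2, h)
        u = _duct_series_profile(y, z, W, H, n_terms=n_terms)
    elif method == "poisson":
        h = spacing if spacing is not None else 0.5
        y, z, u = _poisson_profile(W, H, h)
    else:
        raise ValueError(f"unknown flow method: {method!r}")
    field_ = FlowField(geometry=geometry, ux=u, spacing=h, flow_rate=flow_rate,
                       method=method, y=y, z=z)
    raw_flux = field_.flux()
    if flow_rate == 0:
        field_.ux = np.zeros_like(u)
    else:
        if raw_flux <= 0:
            raise RuntimeError("flow solve failed: non-positive raw flux")
        field_.ux = u * (field_.flow_rate_um3_s / raw_flux)
    return field_
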