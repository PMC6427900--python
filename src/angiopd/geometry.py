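"""Radial geometry, the incompressibility-driven velocity field, and the
free boundary.

The constant-total-density constraint theta = sum of cell densities turns the
summed cell reactions S(r) into a divergence constraint theta * div(u) = S.
Under spherical symmetry this integrates in closed form,

    u(r) = 1/(theta r^2) * int_0^r s^2 S(s) ds,

which is evaluated exactly for piecewise-linear S (the r^2 weight is
integrated analytically on each interval, so there is no 0/0 at the origin).
The tumor boundary R(t) moves with u(R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RadialGrid", "velocity_from_divergence", "advance_boundary",
    "tumor_volume", "node_volumes", "face_radii", "BoundaryCollapse",
]


class BoundaryCollapse(Exception):
    """The free boundary shrank to (or below) zero: full tumor regression."""


@dataclass
class RadialGrid:
    """Moving radial mesh: node radii (cm), node velocities (cm/day),
    boundary radius R = r[-1], current time t (day)."""

    r: np.ndarray
    u: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.u.shape:
            raise ValueError("r and u must be matching 1-D arrays")
        if self.r[0] != 0.0:
            raise ValueError("grid must start at r = 0")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("grid nodes must be strictly increasing")

    @property
    def R(self) -> float:
        return float(self.r[-1])

    @property
    def n_nodes(self) -> int:
        return self.r.size

    def copy(self) -> "RadialGrid":
        return RadialGrid(self.r.copy(), self.u.copy(), self.t)

    @classmethod
    def uniform(cls, R: float, n_nodes: int, t: float = 0.0) -> "RadialGrid":
        r = np.linspace(0.0, R, n_nodes)
        return cls(r=r, u=np.zeros(n_nodes), t=t)


def tumor_volume(R: float) -> float:
    """Spherical tumor volume (cm^3)."""
    if R < 0:
        raise ValueError("radius must be non-negative")
    return 4.0 / 3.0 * np.pi * R ** 3


def face_radii(r: np.ndarray) -> np.ndarray:
    """Midpoint interface radii bounding each node's control volume,
    including the domain ends: [0, (r0+r1)/2, ..., R]."""
    f = np.empty(r.size + 1)
    f[0] = r[0]
    f[-1] = r[-1]
    f[1:-1] = 0.5 * (r[:-1] + r[1:])
    return f


def node_volumes(r: np.ndarray) -> np.ndarray:
    """Control-volume measures (r_{i+1/2}^3 - r_{i-1/2}^3)/3 per node.

    Multiplied by 4*pi these are the spherical shell volumes; the 4*pi is
    dropped consistently everywhere.
    """
    f = face_radii(r)
    return np.diff(f ** 3) / 3.0


def velocity_from_divergence(r: np.ndarray, S: np.ndarray, theta: float) -> np.ndarray:
    """Radial velocity from theta * div(u) = S under spherical symmetry.

    ``S`` is the summed cell-equation reaction term sampled at the nodes,
    interpolated linearly between nodes; the moment integral of s^2 S is then
    exact per interval.  u(0) = 0 by symmetry.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    r = np.asarray(r, dtype=float)
    S = np.asarray(S, dtype=float)
    r0, r1 = r[:-1], r[1:]
    S0, S1 = S[:-1], S[1:]
    h = r1 - r0
    # S(s) = a + b s on [r0, r1]; int s^2 (a + b s) ds analytically.
    b = (S1 - S0) / h
    a = S0 - b * r0
    seg = a * (r1 ** 3 - r0 ** 3) / 3.0 + b * (r1 ** 4 - r0 ** 4) / 4.0
    moment = np.concatenate(([0.0], np.cumsum(seg)))
    u = np.zeros_like(r)
    u[1:] = moment[1:] / (theta * r[1:] ** 2)
    return u


def advance_boundary(R: float, u_R: float, tau: float) -> float:
    """Move the free boundary by the (implicit) boundary velocity:
    R_{k+1} = R_k + u_R * tau.  Raises :class:`BoundaryCollapse` if the
    boundary would cross zero (full regression)."""
    if R <= 0:
        raise ValueError("R must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    R_new = R + u_R * tau
    if R_new <= 0:
        raise BoundaryCollapse(f"tumor radius collapsed: {R_new:.3e} cm")
    return R_new
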