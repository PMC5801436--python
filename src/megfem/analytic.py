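"""Closed-form reference solutions.

* the magnetic field of a point dipole inside a spherically symmetric
  conductor, measured outside it (Sarvas formula) — the validation oracle;
* the primary (free-space) dipole field;
* the singularity potential ``u_inf`` of a dipole in an unbounded homogeneous
  conductor and its gradient — the analytic half of the subtraction approach.

The Sarvas field takes no conductivity argument: outside a spherically
symmetric conductor the field is independent of the radial conductivity
profile, and for a radial source it vanishes entirely.  All functions are
vectorized over evaluation points and linear in the dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalDegeneracyError

__all__ = [
    "MU0",
    "Dipole",
    "SensorArray",
    "sarvas_b_field",
    "primary_b_field",
    "singularity_potential",
    "grad_singularity_potential",
]

#: vacuum permeability [T m / A]
MU0 = 4.0e-7 * np.pi


@dataclass(frozen=True)
class Dipole:
    """Point current dipole: position [m] and moment [A m]."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))
        if not np.linalg.norm(self.moment) > 0:
            raise ValueError("dipole moment must be nonzero")


@dataclass
class SensorArray:
    """Point magnetometers: positions [m] and optional unit orientations."""

    positions: np.ndarray
    orientations: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.orientations is not None:
            self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("sensor orientations must be unit vectors")

    def __len__(self) -> int:
        return len(self.positions)

    def radial_frames(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (radial, tangential, tangential) frame per sensor."""
        n = self.positions / np.linalg.norm(self.positions, axis=1, keepdims=True)
        ref = np.where(np.abs(n[:, [2]]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        t1 = np.cross(ref, n)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(n, t1)
        return n, t1, t2


def _points(r: np.ndarray) -> tuple[np.ndarray, bool]:
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    return np.atleast_2d(r), single


def primary_b_field(dipole: Dipole, r: np.ndarray) -> np.ndarray:
    """Free-space field of the point dipole: mu0/(4 pi) M x d / |d|^3."""
    pts, single = _points(r)
    d = pts - dipole.position
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist == 0.0):
        raise NumericalDegeneracyError("primary field evaluated at the dipole position")
    B = MU0 / (4.0 * np.pi) * np.cross(dipole.moment, d) / dist[:, None] ** 3
    return B[0] if single else B


def sarvas_b_field(dipole: Dipole, r: np.ndarray) -> np.ndarray:
    """Field outside a spherically symmetric conductor centered at the origin.

    With a = r - r0, F = a (r a + r^2 - r . r0):

        B(r) = mu0 / (4 pi F^2) (F M x r0 - (M x r0 . r) grad F)

    Independent of the conductivity profile by construction; zero for radial
    sources (M parallel to r0).
    """
    pts, single = _points(r)
    r0 = dipole.position
    M = dipole.moment
    a_vec = pts - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(pts, axis=1)
    if np.any(a == 0.0):
        raise NumericalDegeneracyError("field point coincides with the dipole")
    adotr = np.einsum("ij,ij->i", a_vec, pts)
    F = a * (rn * a + rn**2 - pts @ r0)
    if np.any(np.abs(F) < 1e-13 * a * rn * (a + rn)):
        raise NumericalDegeneracyError("Sarvas denominator F vanishes at a field point")
    gradF = (a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[:, None] * pts - (
        a + 2.0 * rn + adotr / a
    )[:, None] * r0
    Mxr0 = np.cross(M, r0)
    B = MU0 / (4.0 * np.pi * F[:, None] ** 2) * (
        F[:, None] * Mxr0[None, :] - (pts @ Mxr0)[:, None] * gradF
    )
    return B[0] if single else B


def singularity_potential(dipole: Dipole, sigma_inf: float, r: np.ndarray) -> np.ndarray:
    """Dipole potential in an unbounded homogeneous conductor:
    u_inf(r) = M . (r - r0) / (4 pi sigma_inf |r - r0|^3)."""
    if not sigma_inf > 0:
        raise ValueError("sigma_inf must be positive")
    pts, single = _points(r)
    d = pts - dipole.position
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist == 0.0):
        raise NumericalDegeneracyError("u_inf evaluated at the dipole position")
    u = (d @ dipole.moment) / (4.0 * np.pi * sigma_inf * dist**3)
    return u[0] if single else u


def grad_singularity_potential(
    dipole: Dipole, sigma_inf: float, r: np.ndarray
) -> np.ndarray:
    """Analytic gradient of ``singularity_potential``:
    (M / |d|^3 - 3 (M . d) d / |d|^5) / (4 pi sigma_inf)."""
    if not sigma_inf > 0:
        raise ValueError("sigma_inf must be positive")
    pts, single = _points(r)
    d = pts - dipole.position
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist == 0.0):
        raise NumericalDegeneracyError("grad u_inf evaluated at the dipole position")
    M = dipole.moment
    g = (
        M[None, :] / dist[:, None] ** 3
        - 3.0 * (d @ M)[:, None] * d / dist[:, None] ** 5
    ) / (4.0 * np.pi * sigma_inf)
    return g[0] if single else g
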