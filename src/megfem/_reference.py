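"""Reference trilinear hexahedron: shape functions, quadrature and the
pre-integrated matrices used by both the continuous and the interior-penalty
assembly.

All quantities live on the unit cube [0, 1]^3.  Local node ``i`` sits at the
corner ``(a, b, c)`` with ``i = a + 2 b + 4 c``; the trilinear basis is the
tensor product of ``1 - t`` and ``t``.  On a regular mesh of edge length
``h`` every element is an axis-aligned scaled copy of the reference cube, so
physical gradients are reference gradients divided by ``h`` and all element
matrices are reference matrices times a power of ``h``.

Faces are addressed by ``(axis, side)`` with ``side = 0`` the lower and
``side = 1`` the upper face along ``axis``; the flat face slot used in mesh
bookkeeping is ``2 * axis + side``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

NODE_OFFSETS = np.array(
    [[a, b, c] for c in (0, 1) for b in (0, 1) for a in (0, 1)], dtype=np.int64
)


def gauss_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre rule with ``n`` points mapped to [0, 1] (weights sum to 1)."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def shape_values(points: np.ndarray) -> np.ndarray:
    """Trilinear shape values, shape ``(npts, 8)``."""
    p = np.atleast_2d(points)
    one = 1.0 - p
    out = np.empty((p.shape[0], 8))
    for i, (a, b, c) in enumerate(NODE_OFFSETS):
        out[:, i] = (
            (p[:, 0] if a else one[:, 0])
            * (p[:, 1] if b else one[:, 1])
            * (p[:, 2] if c else one[:, 2])
        )
    return out


def shape_gradients(points: np.ndarray) -> np.ndarray:
    """Reference gradients, shape ``(npts, 8, 3)``."""
    p = np.atleast_2d(points)
    one = 1.0 - p
    out = np.empty((p.shape[0], 8, 3))
    for i, off in enumerate(NODE_OFFSETS):
        for d in range(3):
            g = np.ones(p.shape[0])
            for e in range(3):
                if e == d:
                    g *= 1.0 if off[e] else -1.0
                else:
                    g *= p[:, e] if off[e] else one[:, e]
            out[:, i, d] = g
    return out


@lru_cache(maxsize=8)
def volume_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor Gauss rule on the unit cube: points ``(Q, 3)``, weights ``(Q,)``."""
    x, w = gauss_01(order)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    return pts, W


@lru_cache(maxsize=8)
def reference_stiffness(order: int = 2) -> np.ndarray:
    """``\\int_{[0,1]^3} grad(phi_i) . grad(phi_j)``; exact for ``order >= 2``.

    The physical element matrix is ``sigma * h *`` this.
    """
    pts, w = volume_rule(order)
    g = shape_gradients(pts)  # (Q, 8, 3)
    K = np.einsum("q,qia,qja->ij", w, g, g)
    return 0.5 * (K + K.T)


@lru_cache(maxsize=64)
def face_rule(order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """2D Gauss rule on the unit face: points ``(Q, 2)``, weights summing to 1."""
    x, w = gauss_01(order)
    X, Y = np.meshgrid(x, x, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    W = (w[:, None] * w[None, :]).ravel()
    return pts, W


def face_points_3d(axis: int, side: int, pts2d: np.ndarray) -> np.ndarray:
    """Embed 2D face quadrature points into the reference cube."""
    tang = [d for d in range(3) if d != axis]
    out = np.empty((pts2d.shape[0], 3))
    out[:, axis] = float(side)
    out[:, tang[0]] = pts2d[:, 0]
    out[:, tang[1]] = pts2d[:, 1]
    return out


@lru_cache(maxsize=64)
def face_trace(axis: int, side: int, order: int = 2) -> np.ndarray:
    """Shape values on face ``(axis, side)`` at the face rule points, ``(Q, 8)``."""
    pts2d, _ = face_rule(order)
    return shape_values(face_points_3d(axis, side, pts2d))


@lru_cache(maxsize=64)
def face_normal_deriv(axis: int, side: int, order: int = 2) -> np.ndarray:
    """``d phi / d x_axis`` (reference units, sign of +axis) on the face, ``(Q, 8)``."""
    pts2d, _ = face_rule(order)
    return shape_gradients(face_points_3d(axis, side, pts2d))[:, :, axis]


@lru_cache(maxsize=16)
def face_centroid_trace(axis: int, side: int) -> tuple[np.ndarray, np.ndarray]:
    """Shape values and +axis derivative at the face centroid, two ``(8,)`` arrays."""
    p = face_points_3d(axis, side, np.array([[0.5, 0.5]]))
    return shape_values(p)[0], shape_gradients(p)[0, :, axis]


@lru_cache(maxsize=16)
def dg_face_block(axis: int, eta: float, order: int = 2) -> np.ndarray:
    """Interior-penalty face matrix for a face with normal ``+axis``.

    Couples the 16 corner values ``[u_e (lower element), u_f (upper element)]``.
    The physical contribution to the stiffness matrix is
    ``sigma_hat * h *`` this, where ``sigma_hat`` is the harmonic mean of the
    two element conductivities: with the conductivity-weighted average of the
    flux, ``{sigma grad u} . n = (sigma_hat / 2)(dn u_e + dn u_f)``, so both
    the consistency terms and the penalty ``eta * sigma_hat / h`` scale with
    the single scalar ``sigma_hat``.
    """
    _, w = face_rule(order)
    Te = face_trace(axis, 1, order)
    Tf = face_trace(axis, 0, order)
    De = face_normal_deriv(axis, 1, order)
    Df = face_normal_deriv(axis, 0, order)
    T = np.hstack([Te, -Tf])  # jump of v in the +axis direction
    D = np.hstack([De, Df])  # sum of +axis derivatives (the averaged flux / (sigma_hat/2))
    Tw = T * w[:, None]
    cons = Tw.T @ D
    P = -0.5 * (cons + cons.T) + eta * (Tw.T @ T)
    return 0.5 * (P + P.T)


@lru_cache(maxsize=8)
def tent_weights(order: int = 3) -> np.ndarray:
    """Lowest-order Raviart-Thomas 'tent' profile of each of the 6 faces at the
    volume rule points, shape ``(Q, 6)`` with face slot ``2 * axis + side``.

    The basis attached to a face is 1 on that face and decays linearly to 0 on
    the opposite face of each supporting element.
    """
    pts, _ = volume_rule(order)
    out = np.empty((pts.shape[0], 6))
    for axis in range(3):
        out[:, 2 * axis] = 1.0 - pts[:, axis]
        out[:, 2 * axis + 1] = pts[:, axis]
    return out
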