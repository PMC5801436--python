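"""Geometric multigrid for nodal operators on voxel-lattice vertex sets.

The vertices of a regular hexahedral mesh live on an integer lattice, so a
multigrid hierarchy can be built geometrically: each coarse level keeps the
vertices with all-even lattice coordinates, the prolongation is trilinear
interpolation on the lattice (with weights renormalized near the staircase
boundary, so constants are preserved and the Neumann kernel survives
Galerkin coarsening), and coarse operators are Galerkin triple products.
A symmetric V-cycle with damped-Jacobi smoothing and a pinned sparse direct
solve on the coarsest level serves as a preconditioner for conjugate
gradients on pure-Neumann problems.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def pin_dof(A: sp.spmatrix, dof: int = 0) -> sp.csc_matrix:
    """Replace row/column ``dof`` by the identity: fixes the Neumann gauge
    for a direct factorization; exact for compatible right-hand sides."""
    coo = A.tocoo()
    keep = (coo.row != dof) & (coo.col != dof)
    return sp.coo_matrix(
        (
            np.append(coo.data[keep], 1.0),
            (np.append(coo.row[keep], dof), np.append(coo.col[keep], dof)),
        ),
        shape=A.shape,
    ).tocsc()


def _encode(lat: np.ndarray, dims: np.ndarray) -> np.ndarray:
    return (lat[:, 0] * dims[1] + lat[:, 1]) * dims[2] + lat[:, 2]


def lattice_prolongation(lattice: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    """Trilinear prolongation from the all-even-coordinate sub-lattice.

    Returns ``(P, coarse_lattice)`` with ``P`` of shape (n_fine, n_coarse);
    rows are renormalized over the coarse vertices that actually exist.
    """
    lat = lattice - lattice.min(axis=0)
    n = len(lat)
    even = np.all(lat % 2 == 0, axis=1)
    coarse_ids = np.nonzero(even)[0]
    coarse_lat = lat[coarse_ids] // 2
    dims = lat.max(axis=0) + 2
    ckeys = np.sort(_encode(lat[coarse_ids], dims))
    corder = np.argsort(_encode(lat[coarse_ids], dims))
    # coarse column index by encoded key
    ckey_sorted = _encode(lat[coarse_ids], dims)[corder]

    rows, cols, vals = [], [], []
    half = lat / 2.0
    lo = np.floor(half).astype(np.int64)
    frac = half - lo
    for bits in range(8):
        off = np.array([(bits >> d) & 1 for d in range(3)])
        w = np.ones(n)
        for d in range(3):
            w *= frac[:, d] if off[d] else (1.0 - frac[:, d])
        m = w > 0
        target = (lo[m] + off) * 2  # fine-lattice coords of the coarse point
        keys = _encode(target, dims)
        pos = np.searchsorted(ckey_sorted, keys)
        pos = np.clip(pos, 0, len(ckey_sorted) - 1)
        exists = ckey_sorted[pos] == keys
        idx = np.nonzero(m)[0][exists]
        rows.append(idx)
        cols.append(corder[pos[exists]])
        vals.append(w[m][exists])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, len(coarse_ids)))
    # renormalize so constants are preserved despite missing boundary parents
    rowsum = np.asarray(P.sum(axis=1)).ravel()
    scale = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    P = sp.diags(scale) @ P
    return P.tocsr(), coarse_lat


class LatticeMultigrid:
    """Symmetric V-cycle preconditioner for a nodal lattice operator."""

    def __init__(
        self,
        A: sp.csr_matrix,
        lattice: np.ndarray,
        min_coarse: int = 3000,
        omega: float = 0.7,
        smooth_steps: int = 2,
    ):
        self.omega = omega
        self.smooth_steps = smooth_steps
        self.levels: list[tuple[sp.csr_matrix, np.ndarray, sp.csr_matrix]] = []
        cur_A = A.tocsr()
        cur_lat = np.asarray(lattice)
        while cur_A.shape[0] > min_coarse:
            P, coarse_lat = lattice_prolongation(cur_lat)
            if P.shape[1] >= cur_A.shape[0] or P.shape[1] == 0:
                break
            dinv = 1.0 / cur_A.diagonal()
            self.levels.append((cur_A, dinv, P))
            cur_A = (P.T @ cur_A @ P).tocsr()
            cur_lat = coarse_lat
        self.coarse_A = cur_A
        self.coarse_lu = spla.splu(pin_dof(cur_A))

    @property
    def shape(self):
        A = self.levels[0][0] if self.levels else self.coarse_A
        return A.shape

    def _coarse_solve(self, b: np.ndarray) -> np.ndarray:
        bb = b - b.mean()
        bb[0] = 0.0
        x = self.coarse_lu.solve(bb)
        return x - x.mean()

    def _cycle(self, level: int, b: np.ndarray) -> np.ndarray:
        if level == len(self.levels):
            return self._coarse_solve(b)
        A, dinv, P = self.levels[level]
        x = np.zeros_like(b)
        for _ in range(self.smooth_steps):
            x += self.omega * dinv * (b - A @ x)
        r = b - A @ x
        x += P @ self._cycle(level + 1, P.T @ r)
        for _ in range(self.smooth_steps):
            x += self.omega * dinv * (b - A @ x)
        return x

    def apply(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, np.asarray(b, dtype=float))

    def as_linear_operator(self) -> spla.LinearOperator:
        n = self.shape[0]
        return spla.LinearOperator((n, n), matvec=self.apply)
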