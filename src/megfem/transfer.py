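"""MEG transfer matrices.

With ``K u = j`` the assembled EEG system and ``S`` a secondary-field
integration matrix, the field of any source is ``S K^{-1} j``.  Since ``K``
is symmetric, the dense transfer matrix ``B_MEG = S K^{-1}`` is obtained by
solving ``K x = (row of S)^T`` once per sensor-component row; afterwards
every additional dipole costs one matrix-vector product with its right-hand
side instead of a full solve.  Because the integration matrices annihilate
constants, the result is invariant under the Neumann gauge freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_cg import CGSystem
from .eeg_dg import DGSystem
from .errors import SolverError

__all__ = ["TransferMatrix", "compute_transfer", "apply_transfer"]


@dataclass
class TransferMatrix:
    """Rows = 3 x sensors, columns = EEG degrees of freedom."""

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def compute_transfer(
    system: CGSystem | DGSystem,
    S: np.ndarray,
    tol: float = 1e-8,
) -> TransferMatrix:
    """Solve ``K x = S_row`` (mean-removed for the pure-Neumann nullspace)
    for every row of ``S``, sequentially and in deterministic order."""
    rows = np.empty_like(S)
    for r in range(S.shape[0]):
        rhs = S[r] - S[r].mean()
        try:
            rows[r] = system.solve(rhs, tol=tol)
        except SolverError as exc:
            raise SolverError(f"transfer row {r}: {exc}", residual=exc.residual) from exc
    prov = {
        "discretization": type(system).__name__,
        "tol": tol,
        "n_dofs": S.shape[1],
    }
    return TransferMatrix(matrix=rows, provenance=prov)


def apply_transfer(T: TransferMatrix, rhs: np.ndarray) -> np.ndarray:
    """Field of one right-hand side, reshaped to ``(n_sensors, 3)``."""
    rhs = np.asarray(rhs, dtype=float)
    if rhs.shape[0] != T.matrix.shape[1]:
        raise ValueError(
            f"rhs length {rhs.shape[0]} does not match {T.matrix.shape[1]} dofs"
        )
    return (T.matrix @ rhs).reshape(-1, 3)
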