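"""Linear (constant-strain) tetrahedral element kernels.

Voigt convention for strain: (e_xx, e_yy, e_zz, g_xy, g_yz, g_xz) with
engineering shear strains.  All quantities in the mm-N-MPa system.
"""

from __future__ import annotations

import numpy as np

from .mesh import MeshError

__all__ = ["isotropic_D", "tet_B", "element_stiffness"]


def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (Voigt, engineering shear)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def tet_B(X: np.ndarray, elem_id=None) -> tuple[np.ndarray, float]:
    """Strain-displacement operator B (6x12) and volume of one tetrahedron.

    ``X`` is the 4x3 array of node coordinates.  The strain in the element is
    ``B @ u`` with u the 12-vector of nodal displacements (node-major).
    """
    X = np.asarray(X, dtype=float)
    J = X[1:] - X[0]  # rows: edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if vol <= 0 or not np.isfinite(vol):
        raise MeshError(
            f"degenerate tetrahedron{'' if elem_id is None else f' {elem_id}'}: volume {vol:.3g}"
        )
    # gradients of barycentric shape functions
    grads = np.empty((4, 3))
    grads[1:] = np.linalg.inv(J).T
    grads[0] = -grads[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B, vol


def element_stiffness(X: np.ndarray, E: float, nu: float, elem_id=None):
    """12x12 stiffness of a linear tet, plus its B operator and volume.

    Symmetric positive-semidefinite with exactly six zero-energy (rigid-body)
    modes.
    """
    B, vol = tet_B(X, elem_id)
    D = isotropic_D(E, nu)
    K = vol * B.T @ D @ B
    return K, B, vol
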