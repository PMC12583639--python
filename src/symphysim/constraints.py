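"""Kinematic couplings: tie constraints and distributed (reference-point) coupling.

A tie constraint glues a slave surface to a master surface: every slave node's
displacement is the barycentric interpolation of its master facet's nodal
displacements, so tension and compression are transmitted as if the surfaces
were merged.  A distributed coupling spreads a force applied at a reference
point over a surface patch with a statically equivalent resultant and zero
resultant moment about the reference point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["TieConstraint", "TieError", "apply_tie", "distributed_coupling", "build_transform"]


class TieError(ValueError):
    """Slave nodes could not be projected onto the master surface."""


@dataclass
class TieConstraint:
    """Per-slave-node interpolation: u[slave] = sum_k w_k u[master_k]."""

    slave_nodes: np.ndarray  # (s,)
    master_nodes: np.ndarray  # (s, 3) facet node ids
    weights: np.ndarray  # (s, 3) barycentric weights
    distances: np.ndarray  # (s,) projection distances, mm


def _project_point_triangle(p, tri):
    """Closest point of triangle ``tri`` (3x3) to ``p``; returns (bary, dist)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
    rhs = np.array([ab @ ap, ac @ ap])
    det = d[0, 0] * d[1, 1] - d[0, 1] * d[1, 0]
    if det <= 0:
        return np.array([1.0, 0.0, 0.0]), float(np.linalg.norm(ap))
    v = (d[1, 1] * rhs[0] - d[0, 1] * rhs[1]) / det
    w = (d[0, 0] * rhs[1] - d[0, 1] * rhs[0]) / det
    # clip into the barycentric simplex (adequate for near-coincident surfaces)
    v, w = max(v, 0.0), max(w, 0.0)
    s = v + w
    if s > 1.0:
        v, w = v / s, w / s
    bary = np.array([1.0 - v - w, v, w])
    closest = a + v * ab + w * ac
    return bary, float(np.linalg.norm(p - closest))


def apply_tie(
    nodes: np.ndarray,
    master_facets: np.ndarray,
    slave_nodes: np.ndarray,
    tol: float = 1.0,
) -> TieConstraint:
    """Tie each slave node to its nearest master facet.

    Parameters
    ----------
    nodes : (n, 3) array
        Mesh node coordinates, mm.
    master_facets : (f, 3) int array
        Node triples of the master surface triangles.
    slave_nodes : (s,) int array
        Nodes of the slave surface.
    tol : float
        Maximum admissible projection distance, mm.

    Raises
    ------
    TieError
        Listing every orphan slave node farther than ``tol`` from the master
        surface.
    """
    master_facets = np.asarray(master_facets, dtype=int)
    slave_nodes = np.asarray(slave_nodes, dtype=int)
    if master_facets.size == 0 or slave_nodes.size == 0:
        raise TieError("empty master surface or slave node set")
    tri_coords = nodes[master_facets]  # (f, 3, 3)
    centroids = tri_coords.mean(axis=1)
    masters = np.empty((slave_nodes.size, 3), dtype=int)
    weights = np.empty((slave_nodes.size, 3))
    dists = np.empty(slave_nodes.size)
    orphans = []
    for i, sn in enumerate(slave_nodes):
        p = nodes[sn]
        # candidate facets by centroid distance, exact projection on the best few
        order = np.argsort(np.einsum("ij,ij->i", centroids - p, centroids - p))[:16]
        best = (None, None, np.inf)
        for f in order:
            bary, dist = _project_point_triangle(p, tri_coords[f])
            if dist < best[2]:
                best = (f, bary, dist)
        f, bary, dist = best
        if dist > tol:
            orphans.append((int(sn), dist))
            continue
        masters[i] = master_facets[f]
        weights[i] = bary
        dists[i] = dist
    if orphans:
        raise TieError(
            f"{len(orphans)} slave node(s) farther than tol={tol} mm from the master "
            f"surface: {orphans[:10]}"
        )
    return TieConstraint(slave_nodes, masters, weights, dists)


def build_transform(
    n_nodes: int,
    ties: list[TieConstraint],
    fixed_nodes: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse map T from retained DOFs to all DOFs: ``u_full = T @ q``.

    Slave DOFs are expressed through their master weights; fixed DOFs are
    removed (homogeneous supports).  Returns (T, retained_dof_indices).
    """
    ndof = 3 * n_nodes
    slave = np.zeros(n_nodes, dtype=bool)
    for t in ties:
        if slave[t.slave_nodes].any():
            raise TieError("a node appears as slave in more than one tie")
        slave[t.slave_nodes] = True
    for t in ties:
        if slave[t.master_nodes].any():
            raise TieError("tie chains (slave used as master) are not supported")
    fixed = np.zeros(n_nodes, dtype=bool)
    if fixed_nodes is not None:
        fixed[np.asarray(fixed_nodes, dtype=int)] = True
    retained_nodes = ~(slave | fixed)
    retained_dofs = np.flatnonzero(np.repeat(retained_nodes, 3))
    col_of_dof = -np.ones(ndof, dtype=int)
    col_of_dof[retained_dofs] = np.arange(retained_dofs.size)

    rows, cols, vals = [], [], []
    # identity block on retained dofs
    rows.extend(retained_dofs)
    cols.extend(col_of_dof[retained_dofs])
    vals.extend(np.ones(retained_dofs.size))
    for t in ties:
        for sn, mns, ws in zip(t.slave_nodes, t.master_nodes, t.weights):
            for mn, w in zip(mns, ws):
                if fixed[mn]:
                    continue  # master fixed: contribution is zero displacement
                for d in range(3):
                    rows.append(3 * sn + d)
                    cols.append(col_of_dof[3 * mn + d])
                    vals.append(w)
    T = sp.csr_matrix((vals, (rows, cols)), shape=(ndof, retained_dofs.size))
    return T, retained_dofs


def distributed_coupling(
    node_coords: np.ndarray,
    reference_point: np.ndarray,
    force: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Nodal forces statically equivalent to ``force`` at ``reference_point``.

    The resultant of the returned (k, 3) nodal forces equals ``force`` and
    their resultant moment about the reference point is zero.  With uniform
    weights ``w_i = 1/k`` the construction is

        f_i = w_i F + w_i (lambda x s_i),   s_i = x_i - c,

    where c is the weighted patch centroid and lambda solves the weighted
    moment equation ``A lambda = (ref - c) x F`` with the patch inertia
    ``A = sum w_i (|s_i|^2 I - s_i s_i^T)``.

    Raises
    ------
    ValueError
        For an empty patch or a collinear patch (singular inertia).
    """
    X = np.asarray(node_coords, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("distributed coupling needs a non-empty surface patch")
    F = np.asarray(force, dtype=float)
    ref = np.asarray(reference_point, dtype=float)
    k = X.shape[0]
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float) / np.sum(weights)
    c = w @ X
    s = X - c
    f = w[:, None] * F
    if k > 1:
        A = np.einsum("i,i->", w, np.einsum("ij,ij->i", s, s)) * np.eye(3) - np.einsum(
            "i,ij,ik->jk", w, s, s
        )
        m_target = np.cross(ref - c, F)
        try:
            lam = np.linalg.solve(A, m_target)
        except np.linalg.LinAlgError:
            lam, *_ = np.linalg.lstsq(A, m_target, rcond=None)
        f = f + w[:, None] * np.cross(lam, s)
    return f
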