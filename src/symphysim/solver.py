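"""Incremental small-deformation FE solver with elastoplastic-softening bone.

The solver assembles linear-tetrahedron stiffness over the whole mesh, reduces
the system through tie constraints and fixed supports, adds grounded springs,
and applies the load in increments (initial fraction 0.05 of the total load,
then steps of at most 0.1).  Within each increment the nonlinear bone response
is handled by secant-modulus iteration: every bone element's modulus is
updated to ``sigma(eps_eff)/eps_eff`` from its density-dependent uniaxial
stress-strain curve, where ``eps_eff = 3/(2(1+nu)) * sqrt(2/3 e':e')`` is the
von-Mises-equivalent strain scaled so that the elastic branch reproduces
``sigma = E eps`` in uniaxial stress.  Iteration stops when the global
equilibrium residual with the updated moduli falls below the relative
tolerance.

The interpubic disc uses the near-incompressible linearization of its
Mooney-Rivlin law and stays linear elastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import materials as mat
from .constraints import apply_tie, build_transform, distributed_coupling
from .loadcase import LoadCase
from .mesh import FEMesh, MeshError

__all__ = [
    "ElementMaterials",
    "Solution",
    "SolverError",
    "NonConvergenceError",
    "solve",
    "reaction_at",
    "reaction_magnitude",
]


class SolverError(RuntimeError):
    pass


class NonConvergenceError(SolverError):
    def __init__(self, msg, residual, increment):
        super().__init__(f"{msg} (last residual {residual:.3e} at load factor {increment:.3g})")
        self.residual = residual
        self.increment = increment


@dataclass
class ElementMaterials:
    """Per-element elastic and (optional) softening-curve parameters.

    Bone elements carry the piecewise uniaxial curve of
    :func:`symphysim.materials.bone_curve` flattened into arrays for
    vectorized secant updates; disc (or other linear) elements have
    ``has_curve = False`` and keep their initial modulus.
    """

    E0: np.ndarray  # (m,) initial modulus, MPa
    nu: np.ndarray  # (m,)
    has_curve: np.ndarray  # (m,) bool
    eps_y: np.ndarray  # yield strain
    sigma_y: np.ndarray
    eps_ab: np.ndarray  # softening onset strain
    eps_end: np.ndarray  # softening terminus strain
    sigma_min: np.ndarray
    rho: np.ndarray | None = None  # apparent density, g/cm^3 (bone only)

    @classmethod
    def from_density_field(
        cls,
        mesh: FEMesh,
        rho_ct: np.ndarray,
        mr: mat.MooneyRivlinParams = mat.MooneyRivlinParams(),
        disc_nu: float = 0.475,
        floor: float = mat.DENSITY_FLOOR,
    ) -> "ElementMaterials":
        """Build per-element materials from a CT-density field.

        ``rho_ct`` is per-element calibration density; entries for disc
        elements are ignored (may be NaN).  Bone densities are calibrated,
        floored and classified; densities too low for the softening law stay
        elastic.
        """
        m = mesh.n_elements
        E0 = np.empty(m)
        nu = np.empty(m)
        has_curve = np.zeros(m, dtype=bool)
        eps_y = np.zeros(m)
        sigma_y = np.zeros(m)
        eps_ab = np.full(m, np.inf)
        eps_end = np.full(m, np.inf)
        sigma_min = np.zeros(m)
        rho_out = np.full(m, np.nan)

        disc = mesh.regions == "disc"
        E_d, nu_d = mat.disc_linear_elastic(mr, disc_nu)
        E0[disc] = E_d
        nu[disc] = nu_d

        bone_ix = np.flatnonzero(~disc)
        rho = np.maximum(mat.density_from_ct(np.asarray(rho_ct, dtype=float)[bone_ix]), floor)
        rho_out[bone_ix] = rho
        for e, r in zip(bone_ix, rho):
            E0[e] = mat.elastic_modulus(r)
            nu[e] = mat.POISSON_BONE
            try:
                curve = mat.bone_curve(r)
            except mat.DegenerateMaterialError:
                continue  # stays elastic
            eps = curve.strains
            sig = curve.stresses
            has_curve[e] = True
            eps_y[e], sigma_y[e] = eps[1], sig[1]
            if len(eps) > 2:
                eps_ab[e] = eps[2]
                eps_end[e], sigma_min[e] = eps[3], sig[3]
            else:  # perfectly plastic, no softening stage
                sigma_min[e] = sig[1]
        return cls(E0, nu, has_curve, eps_y, sigma_y, eps_ab, eps_end, sigma_min, rho_out)

    def curve_stress(self, eps_eff: np.ndarray) -> np.ndarray:
        """Vectorized piecewise uniaxial stress at effective strain (bone curve)."""
        e = np.abs(eps_eff)
        softening = np.isfinite(self.eps_end) & (self.eps_end > self.eps_ab)
        ab = np.where(softening, self.eps_ab, 0.0)
        end = np.where(softening, self.eps_end, 1.0)
        soft_slope = np.where(softening, (self.sigma_min - self.sigma_y) / (end - ab), 0.0)
        s = np.where(
            e <= self.eps_y,
            self.E0 * e,
            np.where(
                e <= self.eps_ab,
                self.sigma_y,
                np.where(
                    e <= self.eps_end,
                    self.sigma_y + soft_slope * (e - ab),
                    self.sigma_min,
                ),
            ),
        )
        return s

    def secant_modulus(self, eps_eff: np.ndarray) -> np.ndarray:
        """Per-element secant modulus at the given effective strain."""
        E = self.E0.copy()
        act = self.has_curve & (np.abs(eps_eff) > self.eps_y)
        if act.any():
            e = np.abs(eps_eff[act])
            E[act] = self.curve_stress(eps_eff)[act] / e
        return E


# ---------------------------------------------------------------------------
# Vectorized element operators
# ---------------------------------------------------------------------------


def _element_operators(mesh: FEMesh):
    """Shape gradients (m,4,3), volumes (m,), B operators (m,6,12)."""
    X = mesh.nodes[mesh.elements]  # (m, 4, 3)
    J = X[:, 1:, :] - X[:, :1, :]  # (m, 3, 3)
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    bad = np.flatnonzero(vol <= 0)
    if bad.size:
        raise MeshError(f"non-positive volume in elements {bad[:10].tolist()}")
    invJT = np.transpose(np.linalg.inv(J), (0, 2, 1))
    grads = np.empty((mesh.n_elements, 4, 3))
    grads[:, 1:, :] = invJT
    grads[:, 0, :] = -invJT.sum(axis=1)
    B = np.zeros((mesh.n_elements, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return grads, vol, B


def _assemble(mesh: FEMesh, B, vol, E, nu):
    """Global stiffness (3n x 3n, CSR) for per-element isotropic moduli."""
    m = mesh.n_elements
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((m, 6, 6))
    D[:, :3, :3] = lam[:, None, None]
    D[:, [0, 1, 2], [0, 1, 2]] += 2.0 * mu[:, None]
    D[:, [3, 4, 5], [3, 4, 5]] = mu[:, None]
    Ke = np.einsum("e,eji,ejk,ekl->eil", vol, B, D, B, optimize=True)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _internal_forces(mesh: FEMesh, B, vol, E, nu, eps: np.ndarray) -> np.ndarray:
    """Global internal nodal force vector for given moduli and element strains."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    tr = eps[:, 0] + eps[:, 1] + eps[:, 2]
    sig = np.empty_like(eps)
    sig[:, :3] = (lam * tr)[:, None] + 2.0 * mu[:, None] * eps[:, :3]
    sig[:, 3:] = mu[:, None] * eps[:, 3:]
    fe = np.einsum("e,eij,ei->ej", vol, B, sig)  # (m, 12)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    f = np.zeros(3 * mesh.n_nodes)
    np.add.at(f, dofs.ravel(), fe.ravel())
    return f


def _strains(mesh: FEMesh, B, u: np.ndarray) -> np.ndarray:
    """Voigt strains (m, 6) from nodal displacements (n, 3)."""
    ue = u[mesh.elements].reshape(mesh.n_elements, 12)
    return np.einsum("eij,ej->ei", B, ue)


def _effective_strain(eps_voigt: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Scaled von-Mises-equivalent strain (uniaxial-consistent)."""
    e = eps_voigt
    tr = (e[:, 0] + e[:, 1] + e[:, 2]) / 3.0
    d0, d1, d2 = e[:, 0] - tr, e[:, 1] - tr, e[:, 2] - tr
    # engineering shears -> tensor shears
    s0, s1, s2 = e[:, 3] / 2.0, e[:, 4] / 2.0, e[:, 5] / 2.0
    dd = d0**2 + d1**2 + d2**2 + 2.0 * (s0**2 + s1**2 + s2**2)
    eps_q = np.sqrt(2.0 / 3.0 * dd)
    return 3.0 / (2.0 * (1.0 + nu)) * eps_q


def _voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    """(m, 6) Voigt (eng. shear) -> (m, 3, 3) symmetric tensors."""
    t = np.empty(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3] / 2.0
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4] / 2.0
    t[..., 0, 2] = t[..., 2, 0] = v[..., 5] / 2.0
    return t


# ---------------------------------------------------------------------------
# Solution container
# ---------------------------------------------------------------------------


@dataclass
class Solution:
    """Converged FE state: displacements, element fields, support reactions."""

    u: np.ndarray  # (n, 3) mm
    element_stress: np.ndarray  # (m, 3, 3) MPa
    element_strain: np.ndarray  # (m, 3, 3) small-strain tensor
    disp_grad: np.ndarray  # (m, 3, 3) displacement gradient du_i/dx_j
    reactions: dict[str, np.ndarray]  # support set -> total force 3-vector, N
    converged: bool
    increments: list[tuple[float, int, float]] = field(default_factory=list)
    applied_force: np.ndarray | None = None  # resultant of external loads, N
    E_secant: np.ndarray | None = None  # (m,) final secant moduli

    def equilibrium_residual(self) -> float:
        """|sum reactions + applied| / max(1, |applied|)."""
        total = np.sum(list(self.reactions.values()), axis=0) + self.applied_force
        return float(np.linalg.norm(total) / max(1.0, np.linalg.norm(self.applied_force)))


def reaction_magnitude(components) -> float:
    """Euclidean magnitude sqrt(Fx^2 + Fy^2 + Fz^2) of a reaction force, N."""
    c = np.asarray(components, dtype=float)
    return float(np.sqrt(np.sum(c**2)))


def reaction_at(solution: Solution, support_set: str) -> tuple[np.ndarray, float]:
    """Total reaction force 3-vector and magnitude at a named support set."""
    if support_set not in solution.reactions:
        raise KeyError(
            f"unknown support set {support_set!r}; available: {sorted(solution.reactions)}"
        )
    f = solution.reactions[support_set]
    return f, reaction_magnitude(f)


# ---------------------------------------------------------------------------
# Main solve
# ---------------------------------------------------------------------------


def _load_schedule(initial: float, maximum: float) -> list[float]:
    factors = [min(initial, 1.0)]
    while factors[-1] < 1.0 - 1e-12:
        factors.append(min(factors[-1] + maximum, 1.0))
    return factors


def _external_forces(mesh: FEMesh, case: LoadCase) -> np.ndarray:
    """(n, 3) nodal force vector at full load."""
    f = np.zeros((mesh.n_nodes, 3))
    for pl in case.point_loads:
        patch = mesh.node_sets[pl.surface_set]
        f[patch] += distributed_coupling(
            mesh.nodes[patch], np.asarray(pl.reference_point, float), np.asarray(pl.force, float)
        )
    for ml in case.muscle_loads:
        patch = mesh.node_sets[ml.attachment_set]
        centroid = mesh.nodes[patch].mean(axis=0)
        f[patch] += distributed_coupling(mesh.nodes[patch], centroid, np.asarray(ml.force, float))
    return f


def _spring_matrix(mesh: FEMesh, case: LoadCase) -> tuple[sp.csr_matrix, dict[str, np.ndarray]]:
    """Diagonal spring stiffness and per-set per-node stiffness map.

    The total patch stiffness per translational axis equals the configured
    scalar, distributed equally across the patch nodes.
    """
    ndof = 3 * mesh.n_nodes
    diag = np.zeros(ndof)
    per_node = {}
    for s in case.springs:
        nodes = mesh.node_sets[s.node_set]
        if nodes.size == 0:
            raise SolverError(f"spring set {s.node_set!r} is empty")
        k_node = s.stiffness / nodes.size
        for d in range(3):
            diag[3 * nodes + d] += k_node
        per_node[s.node_set] = (nodes, k_node)
    return sp.diags(diag).tocsr(), per_node


def solve(
    mesh: FEMesh,
    em: ElementMaterials,
    case: LoadCase,
    ties: list | None = None,
    tie_tol: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 40,
    callback=None,
) -> Solution:
    """Run the incremental secant solve for one load case.

    Parameters
    ----------
    mesh, em, case
        Mesh with named sets, per-element materials, declarative load case.
    ties
        Pre-built :class:`~symphysim.constraints.TieConstraint` objects; if
        None, ties are built from ``symphysis_interface_left/right`` slave
        node sets against the matching bone surface facet sets when present.
    tol
        Relative global-equilibrium tolerance per increment.

    Raises
    ------
    NonConvergenceError
        With the last residual and load factor if an increment fails.
    SolverError
        If supports leave rigid-body modes (singular reduced system).
    """
    case.validate_against(mesh)
    if not case.fixed_sets:
        raise SolverError("at least one fully fixed support set is required")

    if ties is None:
        ties = []
        for side in ("left", "right"):
            slave_name = f"symphysis_interface_{side}"
            master_name = f"bone_{side}_symphysis_face"
            if slave_name in mesh.node_sets and master_name in mesh.facet_sets:
                ties.append(
                    apply_tie(
                        mesh.nodes,
                        mesh.facet_sets[master_name],
                        mesh.node_sets[slave_name],
                        tol=tie_tol,
                    )
                )

    fixed_nodes = np.unique(np.concatenate([mesh.node_sets[s] for s in case.fixed_sets]))
    T, _ = build_transform(mesh.n_nodes, ties, fixed_nodes)

    grads, vol, B = _element_operators(mesh)
    S, spring_map = _spring_matrix(mesh, case)
    f_full = _external_forces(mesh, case)
    f_vec = f_full.ravel()

    E_sec = em.E0.copy()
    u = np.zeros(3 * mesh.n_nodes)
    increments = []
    K = None
    prev_factor = 0.0
    eps_eff = None
    for factor in _load_schedule(case.initial_increment, case.max_increment):
        if eps_eff is not None and prev_factor > 0:
            # warm start: extrapolate strains proportionally to the load factor
            E_sec = em.secant_modulus(eps_eff * (factor / prev_factor))
        fr = T.T @ (factor * f_vec)
        fr_norm = np.linalg.norm(fr)
        if fr_norm == 0:
            increments.append((factor, 0, 0.0))
            continue
        converged = False
        res = np.inf
        prev_res = np.inf
        for it in range(max_iter):
            K = _assemble(mesh, B, vol, E_sec, em.nu)
            Kr = (T.T @ ((K + S) @ T)).tocsc()
            try:
                lu = spla.splu(Kr)
            except RuntimeError as exc:  # singular factorization
                raise SolverError(
                    f"singular system at load factor {factor:.3g}: check supports and "
                    f"tie constraints ({exc})"
                ) from exc
            q = lu.solve(fr)
            u = T @ q
            eps = _strains(mesh, B, u.reshape(-1, 3))
            eps_eff = _effective_strain(eps, em.nu)
            E_new = em.secant_modulus(eps_eff)
            # residual with the *updated* state measures self-consistency:
            # r = f_int(E_new; u) + S u - factor f  (internal forces, no matrix)
            r = T.T @ (_internal_forces(mesh, B, vol, E_new, em.nu, eps) + S @ u - factor * f_vec)
            res = float(np.linalg.norm(r) / fr_norm)
            if callback is not None:
                callback(factor, it, res)
            if res < tol:
                E_sec = E_new
                converged = True
                increments.append((factor, it + 1, res))
                break
            # full secant update while the residual decreases, relaxed otherwise
            omega = 1.0 if res < prev_res else 0.5
            E_sec = np.where(em.has_curve, E_sec + omega * (E_new - E_sec), E_sec)
            prev_res = res
        if not converged:
            raise NonConvergenceError("secant iteration did not converge", res, factor)
        prev_factor = factor

    # final solve consistent with the converged secant moduli, so that the
    # stored state satisfies the linearized equilibrium to machine precision
    K = _assemble(mesh, B, vol, E_sec, em.nu)
    Kr = (T.T @ ((K + S) @ T)).tocsc()
    u = T @ spla.splu(Kr).solve(T.T @ f_vec)

    un = u.reshape(-1, 3)
    eps = _strains(mesh, B, un)
    lam = E_sec * em.nu / ((1.0 + em.nu) * (1.0 - 2.0 * em.nu))
    mu = E_sec / (2.0 * (1.0 + em.nu))
    tr = eps[:, 0] + eps[:, 1] + eps[:, 2]
    sig = np.empty_like(eps)
    sig[:, :3] = (lam * tr)[:, None] + 2.0 * mu[:, None] * eps[:, :3]
    sig[:, 3:] = mu[:, None] * eps[:, 3:]
    # stress tensors keep full (not halved) shear components
    stress = np.empty((mesh.n_elements, 3, 3))
    stress[:, 0, 0] = sig[:, 0]
    stress[:, 1, 1] = sig[:, 1]
    stress[:, 2, 2] = sig[:, 2]
    stress[:, 0, 1] = stress[:, 1, 0] = sig[:, 3]
    stress[:, 1, 2] = stress[:, 2, 1] = sig[:, 4]
    stress[:, 0, 2] = stress[:, 2, 0] = sig[:, 5]
    strain = _voigt_to_tensor(eps)
    H = np.einsum("eaj,eak->ejk", un[mesh.elements], grads)

    # support reactions at full load (same K as the final consistent solve)
    r_full = ((K + S) @ u - f_vec).reshape(-1, 3)
    reactions: dict[str, np.ndarray] = {}
    for s in case.fixed_sets:
        reactions[s] = r_full[mesh.node_sets[s]].sum(axis=0)
    for name, (nodes, k_node) in spring_map.items():
        reactions[name] = -(k_node * un[nodes]).sum(axis=0)

    return Solution(
        u=un,
        element_stress=stress,
        element_strain=strain,
        disp_grad=H,
        reactions=reactions,
        converged=True,
        increments=increments,
        applied_force=f_full.sum(axis=0),
        E_secant=E_sec,
    )
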