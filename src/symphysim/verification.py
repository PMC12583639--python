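"""Built-in verification problems with independent reference solutions.

Each function sets up a small problem whose answer is known from theory or
exhaustive enumeration — an affine patch test, an Euler-Bernoulli cantilever,
a brute-force activation search, a finite-difference check of the disc energy
— runs the package's own machinery on it and returns the discrepancy.
"""

from __future__ import annotations

import numpy as np

from . import materials as mat
from . import muscles as mu
from . import solver as FE
from .loadcase import LoadCase, PointLoad
from .mesh import FEMesh
from .synthetic import _box_tets

__all__ = [
    "patch_test_max_error",
    "cantilever_rel_error",
    "static_opt_grid_gap",
    "mr_consistency_max_rel_err",
    "yield_branch_gap",
]


def _uniform_materials(mesh: FEMesh, E: float, nu: float) -> FE.ElementMaterials:
    m = mesh.n_elements
    return FE.ElementMaterials(
        E0=np.full(m, E),
        nu=np.full(m, nu),
        has_curve=np.zeros(m, dtype=bool),
        eps_y=np.zeros(m),
        sigma_y=np.zeros(m),
        eps_ab=np.full(m, np.inf),
        eps_end=np.full(m, np.inf),
        sigma_min=np.zeros(m),
    )


def patch_test_max_error(seed: int = 0, n: int = 3) -> float:
    """Affine patch test on a structured cube.

    An affine displacement imposed on the boundary of a homogeneous elastic
    cube must be reproduced exactly at interior nodes by linear tetrahedra.
    Returns the max nodal error relative to the field magnitude.
    """
    import scipy.sparse.linalg as spla

    ax = np.linspace(0.0, 1.0, n + 1)
    nodes, tets = _box_tets(ax, ax, ax)
    mesh = FEMesh(nodes=nodes, elements=tets, regions=np.full(len(tets), "bone_right"))
    rng = np.random.default_rng(seed)
    A = 0.01 * rng.standard_normal((3, 3))
    boundary = np.flatnonzero(
        np.any(np.isclose(nodes, 0.0) | np.isclose(nodes, 1.0), axis=1)
    )
    em = _uniform_materials(mesh, 2000.0, 0.3)
    _, vol, B = FE._element_operators(mesh)
    K = FE._assemble(mesh, B, vol, em.E0, em.nu)
    ndof = 3 * mesh.n_nodes
    fixed = (3 * boundary[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(ndof), fixed)
    u = np.zeros(ndof)
    u[fixed] = (A @ nodes[boundary].T).T.ravel()
    u[free] = spla.spsolve(K[free][:, free].tocsc(), -(K[free][:, fixed] @ u[fixed]))
    expected = (A @ nodes.T).T.ravel()
    return float(np.abs(u - expected).max() / max(np.abs(expected).max(), 1e-30))


def cantilever_rel_error(
    length: float = 100.0,
    depth: float = 10.0,
    nx: int = 80,
    nc: int = 12,
    E: float = 2000.0,
    P: float = 20.0,
) -> float:
    """Tip deflection of a slender elastic cantilever vs. PL^3/3EI.

    Aspect ratio length/depth = 10 by default, where the Euler-Bernoulli
    closed form is accurate (shear deflection < 1%).
    """
    nodes, tets = _box_tets(
        np.linspace(0, length, nx + 1),
        np.linspace(-depth / 2, depth / 2, nc + 1),
        np.linspace(-depth / 2, depth / 2, nc + 1),
    )
    mesh = FEMesh(nodes=nodes, elements=tets, regions=np.full(len(tets), "bone_right"))
    root = np.flatnonzero(np.isclose(nodes[:, 0], 0.0))
    tip = np.flatnonzero(np.isclose(nodes[:, 0], length))
    mesh.node_sets["root"] = root
    mesh.node_sets["tip"] = tip
    case = LoadCase(
        point_loads=[PointLoad((length, 0.0, 0.0), (0.0, -P, 0.0), "tip")],
        fixed_sets=["root"],
        initial_increment=1.0,
        max_increment=1.0,
    )
    sol = FE.solve(mesh, _uniform_materials(mesh, E, 0.3), case)
    I = depth**4 / 12.0
    expected = P * length**3 / (3.0 * E * I)
    got = -sol.u[tip, 1].mean()
    return float(abs(got - expected) / expected)


def static_opt_grid_gap(seed: int = 0, trials: int = 5, step: float = 1e-3) -> float:
    """Max activation gap between the QP solver and exhaustive grid search.

    Random 3-muscle, 2-axis instances; the grid enumerates one activation
    along the constraint null space and solves the two moment equalities
    exactly for the rest, so every candidate is feasible.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(trials):
        ms = [
            mu.MuscleDef(f"m{i}", rng.uniform(80, 300), moment_arms=rng.uniform(-15, 15, 2))
            for i in range(3)
        ]
        R = mu.StaticOptProblem(ms, [0, 0]).moment_matrix()
        Q = R @ rng.uniform(0.1, 0.8, 3)
        sol = mu.solve_static_opt(mu.StaticOptProblem(ms, Q))
        # enumerate along the null direction with the largest component
        _, _, vh = np.linalg.svd(R)
        k = int(np.argmax(np.abs(vh[-1])))
        others = [i for i in range(3) if i != k]
        grid = np.arange(0.01, 1.0 + step / 2, step)
        rhs = Q[:, None] - np.outer(R[:, k], grid)
        dep = np.linalg.solve(R[:, others], rhs)
        ok = np.all((dep >= 0.01 - 1e-9) & (dep <= 1.0 + 1e-9), axis=0)
        obj = grid**2 + (dep**2).sum(axis=0)
        obj[~ok] = np.inf
        j = int(np.argmin(obj))
        best = np.empty(3)
        best[k] = grid[j]
        best[others] = dep[:, j]
        worst = max(worst, float(np.abs(sol.a - best).max()))
    return worst


def mr_consistency_max_rel_err(n: int = 21) -> float:
    """Uniaxial Mooney-Rivlin stress vs. central-difference energy derivative."""
    p = mat.MooneyRivlinParams()

    def W(lam):
        return mat.mr_energy(lam**2 + 2.0 / lam, 2.0 * lam + 1.0 / lam**2, p)

    worst = 0.0
    for lam in np.linspace(0.85, 1.25, n):
        if abs(lam - 1.0) < 1e-9:
            continue
        h = 1e-6
        oracle = lam * (W(lam + h) - W(lam - h)) / (2 * h)
        got = mat.mr_uniaxial_stress(lam, p)
        worst = max(worst, abs(got - oracle) / abs(oracle))
    return float(worst)


def yield_branch_gap(rho: float = mat.RHO_THRESHOLD) -> float:
    """|sigma_y difference| between the two printed power laws at a density."""
    return float(abs(57.75 * rho**1.73 - 76.5 * rho**6.7))
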