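"""Element kernels, kinematic couplings and the incremental solver."""

import numpy as np
import pytest

from symphysim import constraints as C
from symphysim import solver as FE
from symphysim.elements import element_stiffness, tet_B
from symphysim.loadcase import LoadCase, PointLoad, SpringSupport
from symphysim.mesh import FEMesh, MeshError
from symphysim.synthetic import _box_tets

from conftest import unit_cube_mesh


UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestElementStiffness:
    def test_six_rigid_modes(self):
        K, _, _ = element_stiffness(UNIT_TET, E=1000.0, nu=0.3)
        w = np.linalg.eigvalsh(K)
        assert np.all(np.abs(w[:6]) < 1e-9 * w[-1])
        assert np.all(w[6:] > 1e-9 * w[-1])

    def test_rigid_translation_gives_zero_force(self):
        K, _, _ = element_stiffness(UNIT_TET, E=1000.0, nu=0.3)
        u = np.tile([1.0, -2.0, 0.5], 4)
        assert np.linalg.norm(K @ u) < 1e-10 * np.linalg.norm(K)

    def test_degenerate_tet_raises(self):
        flat = UNIT_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(MeshError):
            tet_B(flat, elem_id=7)

    def test_affine_field_strain_recovery(self):
        """Constant-strain element reproduces an affine map's strain exactly."""
        rng = np.random.default_rng(0)
        A = 0.01 * rng.standard_normal((3, 3))
        X = rng.random((4, 3)) + UNIT_TET
        B, _ = tet_B(X)
        u = (A @ X.T).T.ravel()
        eps = B @ u
        sym = 0.5 * (A + A.T)
        expected = np.array(
            [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]]
        )
        np.testing.assert_allclose(eps, expected, atol=1e-14)


class TestDistributedCoupling:
    def test_symmetric_ring_axial_force_equal_shares(self):
        t = np.linspace(0, 2 * np.pi, 9)[:-1]
        ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        f = C.distributed_coupling(ring, [0, 0, 0], [0, 0, 8.0])
        np.testing.assert_allclose(f, np.tile([0, 0, 1.0], (8, 1)), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_resultant_and_moment(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((12, 3)) * 10
        ref = rng.random(3) * 10
        force = rng.standard_normal(3) * 100
        f = C.distributed_coupling(pts, ref, force)
        np.testing.assert_allclose(f.sum(axis=0), force, rtol=1e-10)
        moments = np.cross(pts - ref, f).sum(axis=0)
        np.testing.assert_allclose(moments, 0.0, atol=1e-8 * np.abs(force).max() * 10)

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            C.distributed_coupling(np.empty((0, 3)), [0, 0, 0], [1, 0, 0])


class TestTieConstraint:
    def test_coincident_grids_identity_pairing(self):
        ax = np.linspace(0, 1, 3)
        nodes, tets = _box_tets(ax, ax, ax)
        from symphysim.mesh import surface_facets

        facets = surface_facets(tets)
        face = facets[np.all(np.isclose(nodes[facets][:, :, 2], 0.0), axis=1)]
        slave = np.flatnonzero(np.isclose(nodes[:, 2], 0.0))
        tie = C.apply_tie(nodes, face, slave, tol=1e-6)
        # every slave node coincides with a master vertex: one unit weight
        assert np.allclose(np.sort(tie.weights, axis=1)[:, -1], 1.0, atol=1e-9)
        assert np.all(tie.distances < 1e-12)

    def test_centroid_slave_gets_barycentric_thirds(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1 / 3, 1 / 3, 0.0]])
        tie = C.apply_tie(nodes, np.array([[0, 1, 2]]), np.array([3]), tol=1e-6)
        np.testing.assert_allclose(tie.weights[0], [1 / 3, 1 / 3, 1 / 3], atol=1e-9)

    def test_orphan_slave_raises_with_listing(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [5.0, 5.0, 5.0]])
        with pytest.raises(C.TieError, match="slave node"):
            C.apply_tie(nodes, np.array([[0, 1, 2]]), np.array([3]), tol=0.5)


def _two_block_mesh(merged: bool):
    """Two stacked unit-cube blocks, either merged or as separate tied bodies."""
    ax = np.linspace(0.0, 1.0, 3)
    if merged:
        az = np.linspace(0.0, 2.0, 5)
        nodes, tets = _box_tets(ax, ax, az)
        return FEMesh(nodes=nodes, elements=tets, regions=np.full(len(tets), "bone_right")), []
    n1, t1 = _box_tets(ax, ax, np.linspace(0.0, 1.0, 3))
    n2, t2 = _box_tets(ax, ax, np.linspace(1.0, 2.0, 3))
    nodes = np.vstack([n1, n2])
    tets = np.vstack([t1, t2 + len(n1)])
    regions = np.concatenate([np.full(len(t1), "bone_right"), np.full(len(t2), "bone_left")])
    mesh = FEMesh(nodes=nodes, elements=tets, regions=regions)
    from symphysim.mesh import surface_facets

    facets = surface_facets(t1)
    master = facets[np.all(np.isclose(n1[facets][:, :, 2], 1.0), axis=1)]
    slave = len(n1) + np.flatnonzero(np.isclose(n2[:, 2], 1.0))
    ties = [C.apply_tie(nodes, master, slave, tol=1e-6)]
    return mesh, ties


def _uniform_em(mesh, E=2000.0, nu=0.3):
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


class TestTiedBlocks:
    def test_tension_matches_merged_mesh(self):
        """Two glued blocks under tension behave like one merged mesh."""
        results = {}
        for merged in (True, False):
            mesh, ties = _two_block_mesh(merged)
            bottom = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 0.0))
            top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 2.0))
            mesh.node_sets["bottom"] = bottom
            mesh.node_sets["top"] = top
            case = LoadCase(
                point_loads=[PointLoad((0.5, 0.5, 2.0), (0.0, 0.0, 100.0), "top")],
                fixed_sets=["bottom"],
            )
            sol = FE.solve(mesh, _uniform_em(mesh), case, ties=ties)
            results[merged] = sol.u[top].mean(axis=0)
        np.testing.assert_allclose(results[True], results[False], rtol=1e-6, atol=1e-9)

    def test_no_gap_at_interface(self):
        mesh, ties = _two_block_mesh(False)
        bottom = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 0.0))
        top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 2.0))
        mesh.node_sets["bottom"] = bottom
        mesh.node_sets["top"] = top
        case = LoadCase(
            point_loads=[PointLoad((0.5, 0.5, 2.0), (0.0, 0.0, 100.0), "top")],
            fixed_sets=["bottom"],
        )
        sol = FE.solve(mesh, _uniform_em(mesh), case, ties=ties)
        # matching nodes on the two sides of the interface move together
        lower = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 1.0))
        side_a = [n for n in lower if n < 9 * 3]  # block-1 nodes (9 per layer, 3 layers)
        gap = 0.0
        for na in side_a:
            match = [
                nb
                for nb in lower
                if nb >= 27 and np.allclose(mesh.nodes[na], mesh.nodes[nb])
            ]
            assert match
            gap = max(gap, np.abs(sol.u[na] - sol.u[match[0]]).max())
        assert gap < 1e-10


class TestPatchTest:
    @pytest.mark.parametrize("seed", [0, 3])
    def test_affine_displacement_recovered(self, seed):
        """Imposing an affine field on the boundary reproduces it everywhere."""
        mesh = unit_cube_mesh(3)
        rng = np.random.default_rng(seed)
        A = 0.01 * rng.standard_normal((3, 3))
        boundary = np.flatnonzero(
            np.any(np.isclose(mesh.nodes, 0.0) | np.isclose(mesh.nodes, 1.0), axis=1)
        )
        em = _uniform_em(mesh)
        grads, vol, B = FE._element_operators(mesh)
        K = FE._assemble(mesh, B, vol, em.E0, em.nu)
        ndof = 3 * mesh.n_nodes
        u = np.zeros(ndof)
        fixed_dofs = (3 * boundary[:, None] + np.arange(3)).ravel()
        u_b = (A @ mesh.nodes[boundary].T).T.ravel()
        free = np.setdiff1d(np.arange(ndof), fixed_dofs)
        import scipy.sparse.linalg as spla

        rhs = -(K[:, fixed_dofs] @ u_b)
        u[fixed_dofs] = u_b
        u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs[free])
        expected = (A @ mesh.nodes.T).T.ravel()
        scale = np.abs(expected).max()
        assert np.abs(u - expected).max() < 1e-10 * max(scale, 1.0)


class TestSolver:
    def test_single_spring_hooke(self):
        """One spring-supported patch: reaction = -k u."""
        mesh = unit_cube_mesh(1)
        base = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 0.0))
        top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 1.0))
        mesh.node_sets["base"] = base
        mesh.node_sets["top"] = top
        case = LoadCase(
            point_loads=[PointLoad((0.5, 0.5, 1.0), (0.0, 0.0, 50.0), "top")],
            fixed_sets=["base"],
            springs=[SpringSupport("top", 4285.0)],
        )
        sol = FE.solve(mesh, _uniform_em(mesh, E=1e9), case)
        # near-rigid block: the spring set carries k * u of the patch
        u_top = sol.u[top].mean(axis=0)
        np.testing.assert_allclose(
            sol.reactions["top"], -4285.0 * u_top * 1.0, rtol=1e-6, atol=1e-9
        )

    def test_uniaxial_elastic_stress(self):
        mesh = unit_cube_mesh(1)
        bottom = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 0.0))
        top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 1.0))
        mesh.node_sets["bottom"] = bottom
        mesh.node_sets["top"] = top
        case = LoadCase(
            point_loads=[PointLoad((0.5, 0.5, 1.0), (0.0, 0.0, 10.0), "top")],
            fixed_sets=["bottom"],
        )
        sol = FE.solve(mesh, _uniform_em(mesh, E=2000.0, nu=0.0), case)
        # volume-averaged sigma_zz = F/A = 10 MPa on the unit cross-section
        # (individual constant-strain tets fluctuate around it)
        vols = mesh.volumes()
        mean = float(vols @ sol.element_stress[:, 2, 2] / vols.sum())
        assert mean == pytest.approx(10.0, rel=1e-6)

    def test_equilibrium_of_reactions(self, toy_solutions):
        for sol in toy_solutions.values():
            assert sol.equilibrium_residual() < 1e-6

    def test_incremental_equals_linear_for_elastic(self):
        """With all strains elastic the incremental path ends at the linear solution."""
        mesh, ties = _two_block_mesh(False)
        bottom = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 0.0))
        top = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 2.0))
        mesh.node_sets["bottom"] = bottom
        mesh.node_sets["top"] = top
        case_inc = LoadCase(
            point_loads=[PointLoad((0.5, 0.5, 2.0), (0.0, 0.0, 100.0), "top")],
            fixed_sets=["bottom"],
        )
        case_one = LoadCase(
            point_loads=[PointLoad((0.5, 0.5, 2.0), (0.0, 0.0, 100.0), "top")],
            fixed_sets=["bottom"],
            initial_increment=1.0,
            max_increment=1.0,
        )
        em = _uniform_em(mesh)
        u_inc = FE.solve(mesh, em, case_inc, ties=ties).u
        u_one = FE.solve(mesh, em, case_one, ties=ties).u
        np.testing.assert_allclose(u_inc, u_one, rtol=1e-8, atol=1e-12)

    def test_missing_support_rejected(self):
        mesh = unit_cube_mesh(1)
        mesh.node_sets["top"] = np.flatnonzero(np.isclose(mesh.nodes[:, 2], 1.0))
        case = LoadCase(
            point_loads=[PointLoad((0.5, 0.5, 1.0), (0.0, 0.0, 10.0), "top")],
        )
        with pytest.raises(FE.SolverError):
            FE.solve(mesh, _uniform_em(mesh), case)


class TestCantileverBeamOracle:
    def test_tip_deflection_matches_beam_theory(self):
        """Slender elastic cantilever: tip deflection within 5% of PL^3/3EI."""
        L, hgt, wid = 100.0, 10.0, 10.0
        nx, nc = 80, 12
        nodes, tets = _box_tets(
            np.linspace(0, L, nx + 1),
            np.linspace(-hgt / 2, hgt / 2, nc + 1),
            np.linspace(-wid / 2, wid / 2, nc + 1),
        )
        mesh = FEMesh(nodes=nodes, elements=tets, regions=np.full(len(tets), "bone_right"))
        root = np.flatnonzero(np.isclose(nodes[:, 0], 0.0))
        tip = np.flatnonzero(np.isclose(nodes[:, 0], L))
        mesh.node_sets["root"] = root
        mesh.node_sets["tip"] = tip
        E, P = 2000.0, 20.0
        case = LoadCase(
            point_loads=[PointLoad((L, 0.0, 0.0), (0.0, -P, 0.0), "tip")],
            fixed_sets=["root"],
            initial_increment=1.0,
            max_increment=1.0,
        )
        sol = FE.solve(mesh, _uniform_em(mesh, E=E, nu=0.3), case)
        I = wid * hgt**3 / 12.0
        expected = P * L**3 / (3.0 * E * I)
        got = -sol.u[tip, 1].mean()
        assert got == pytest.approx(expected, rel=0.05)


class TestReactionMagnitude:
    def test_printed_component_composition(self):
        assert FE.reaction_magnitude((-381.5, 463.0, -829.6)) == pytest.approx(
            1023.8, abs=0.05
        )

    def test_unknown_set_raises(self, toy_solutions):
        with pytest.raises(KeyError):
            FE.reaction_at(toy_solutions["reaction_only"], "nope")
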