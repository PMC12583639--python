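import numpy as np
import pytest

from symphysim import solver as FE
from symphysim import synthetic as S


@pytest.fixture(scope="session")
def toy_params():
    return S.PelvisToyParams(seed=42)


@pytest.fixture(scope="session")
def toy_mesh(toy_params):
    return S.generate_toy_pelvis(toy_params)


@pytest.fixture(scope="session")
def toy_density(toy_mesh, toy_params):
    return S.generate_density(toy_mesh, toy_params)


@pytest.fixture(scope="session")
def toy_materials(toy_mesh, toy_density):
    return FE.ElementMaterials.from_density_field(toy_mesh, toy_density.rho_ct)


@pytest.fixture(scope="session")
def toy_solutions(toy_mesh, toy_materials):
    """Both reference load cases solved once for the whole session."""
    out = {}
    for include_muscles in (False, True):
        case = S.reference_load_case(toy_mesh, include_muscles=include_muscles)
        out[case.name] = FE.solve(toy_mesh, toy_materials, case)
    return out


def unit_cube_mesh(n=2):
    """Structured tet mesh of the unit cube, n cells per side."""
    from symphysim.synthetic import _box_tets

    ax = np.linspace(0.0, 1.0, n + 1)
    nodes, tets = _box_tets(ax, ax, ax)
    from symphysim.mesh import FEMesh

    return FEMesh(nodes=nodes, elements=tets, regions=np.full(len(tets), "bone_right"))
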