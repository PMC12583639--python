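"""Tetrahedral finite-element mesh container with named sets.

Units are millimetres.  Elements are 4-node linear tetrahedra carrying a
region tag (``bone_left``, ``bone_right``, ``disc``); named node sets, element
sets and facet (surface triangle) sets identify boundary patches and muscle
attachment sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FEMesh", "MeshError", "tet_volumes", "surface_facets"]


class MeshError(ValueError):
    pass


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed node order)."""
    a = nodes[elements[:, 1]] - nodes[elements[:, 0]]
    b = nodes[elements[:, 2]] - nodes[elements[:, 0]]
    c = nodes[elements[:, 3]] - nodes[elements[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def surface_facets(elements: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
    """Boundary triangles (node triples, outward order) of an element set.

    A facet is on the surface iff it belongs to exactly one tetrahedron of the
    set.  Local faces are ordered so the outward normal follows the
    right-hand rule for positively oriented tets.
    """
    els = elements if subset is None else elements[np.asarray(subset)]
    # outward-oriented faces of a positive tet (0,1,2,3)
    faces = np.concatenate(
        [
            els[:, [0, 2, 1]],
            els[:, [0, 1, 3]],
            els[:, [1, 2, 3]],
            els[:, [0, 3, 2]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


@dataclass
class FEMesh:
    """Nodes, tetrahedral elements, region tags and named sets."""

    nodes: np.ndarray  # (n, 3) float, mm
    elements: np.ndarray  # (m, 4) int node indices
    regions: np.ndarray  # (m,) str region tag per element
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    elem_sets: dict[str, np.ndarray] = field(default_factory=dict)
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)  # (k, 3) node triples

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        self.regions = np.asarray(self.regions)
        self.node_sets = {k: np.asarray(v, dtype=int) for k, v in self.node_sets.items()}
        self.elem_sets = {k: np.asarray(v, dtype=int) for k, v in self.elem_sets.items()}
        self.facet_sets = {k: np.asarray(v, dtype=int) for k, v in self.facet_sets.items()}

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def region_elements(self, *tags: str) -> np.ndarray:
        """Indices of elements whose region tag is in ``tags``."""
        return np.flatnonzero(np.isin(self.regions, tags))

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.elements)

    def validate(self) -> None:
        """Check element orientation and set references; raise MeshError."""
        vols = self.volumes()
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise MeshError(f"non-positive volume in elements {bad[:10].tolist()}")
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise MeshError("element connectivity references missing nodes")
        for name, s in self.node_sets.items():
            if s.size and (s.min() < 0 or s.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} references missing nodes")
        for name, s in self.elem_sets.items():
            if s.size and (s.min() < 0 or s.max() >= self.n_elements):
                raise MeshError(f"element set {name!r} references missing elements")
        for name, f in self.facet_sets.items():
            if f.size and (f.min() < 0 or f.max() >= self.n_nodes):
                raise MeshError(f"facet set {name!r} references missing nodes")

    def surface(self, region: str | None = None) -> np.ndarray:
        """Boundary facets of the whole mesh or of one region."""
        subset = None if region is None else self.region_elements(region)
        return surface_facets(self.elements, subset)
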