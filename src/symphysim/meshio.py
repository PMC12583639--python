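"""Minimal mesh and field I/O: Gmsh MSH 2.2, legacy VTK, Abaqus-INP subset.

These readers/writers cover exactly what the pipeline needs for tetrahedral
meshes with named sets and element fields:

* **Gmsh MSH 2.2 (ASCII)** — nodes, 4-node tets with a physical region tag,
  ``$PhysicalNames`` for region names.  Node/facet sets are not representable
  in this format and are dropped on write.
* **Legacy VTK (ASCII unstructured grid)** — mesh plus named point vectors
  (e.g. displacement) and cell scalars (e.g. reduced stress) for
  visualization; a matching reader restores the mesh and fields.
* **Abaqus INP subset** — ``*NODE``, ``*ELEMENT, TYPE=C3D4`` per region
  ``ELSET``, ``*NSET``, ``*ELSET`` and ``*SURFACE, TYPE=ELEMENT`` (facet sets
  mapped to element faces S1-S4).  Set names are sanitized to INP identifiers
  and restored verbatim on read where possible.

All files are plain text; indices are 1-based on disk and 0-based in memory.
"""

from __future__ import annotations

import re

import numpy as np

from .mesh import FEMesh

__all__ = [
    "write_msh",
    "read_msh",
    "write_vtk",
    "read_vtk",
    "write_inp",
    "read_inp",
    "write_density_csv",
    "read_density_csv",
]


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2
# ---------------------------------------------------------------------------


def write_msh(mesh: FEMesh, path) -> None:
    """Write nodes/tets with physical region tags in MSH 2.2 ASCII."""
    region_names = sorted(set(mesh.regions.tolist()))
    region_id = {name: i + 1 for i, name in enumerate(region_names)}
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n%d\n" % len(region_names))
        for name, rid in region_id.items():
            f.write(f'3 {rid} "{name}"\n')
        f.write("$EndPhysicalNames\n$Nodes\n%d\n" % mesh.n_nodes)
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.16g} {y:.16g} {z:.16g}\n")
        f.write("$EndNodes\n$Elements\n%d\n" % mesh.n_elements)
        for i, (el, reg) in enumerate(zip(mesh.elements, mesh.regions), start=1):
            rid = region_id[str(reg)]
            f.write(f"{i} 4 2 {rid} {rid} {el[0]+1} {el[1]+1} {el[2]+1} {el[3]+1}\n")
        f.write("$EndElements\n")


def read_msh(path) -> FEMesh:
    """Read an MSH 2.2 ASCII file written by :func:`write_msh` (tets only)."""
    with open(path) as f:
        lines = f.read().splitlines()
    it = iter(lines)
    names = {}
    nodes = []
    elements = []
    regions = []
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split(maxsplit=2)
                names[int(parts[1])] = parts[2].strip('"')
            next(it)
        elif line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(v) for v in parts[1:4]])
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = [int(v) for v in next(it).split()]
                if parts[1] != 4:  # skip non-tet entities
                    continue
                ntags = parts[2]
                tag = parts[3] if ntags else 0
                conn = parts[3 + ntags : 7 + ntags]
                elements.append([c - 1 for c in conn])
                regions.append(names.get(tag, str(tag)))
            next(it)
    return FEMesh(
        nodes=np.asarray(nodes),
        elements=np.asarray(elements, dtype=int),
        regions=np.asarray(regions),
    )


# ---------------------------------------------------------------------------
# Legacy VTK
# ---------------------------------------------------------------------------


def write_vtk(
    mesh: FEMesh,
    path,
    point_vectors: dict[str, np.ndarray] | None = None,
    cell_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write an ASCII legacy-VTK unstructured grid with named fields."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nsymphysim mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            f.write(f"{x:.16g} {y:.16g} {z:.16g}\n")
        f.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for el in mesh.elements:
            f.write(f"4 {el[0]} {el[1]} {el[2]} {el[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        f.write("\n".join(["10"] * mesh.n_elements) + "\n")
        if point_vectors:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_vectors.items():
                f.write(f"VECTORS {name} double\n")
                for v in np.asarray(arr, dtype=float):
                    f.write(f"{v[0]:.16g} {v[1]:.16g} {v[2]:.16g}\n")
        region_ids = {n: i for i, n in enumerate(sorted(set(mesh.regions.tolist())))}
        scalars = {"region_id": np.array([region_ids[str(r)] for r in mesh.regions], float)}
        scalars.update({k: np.asarray(v, dtype=float) for k, v in (cell_scalars or {}).items()})
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in scalars.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{v:.16g}" for v in arr) + "\n")


def read_vtk(path):
    """Read a legacy-VTK file written by :func:`write_vtk`.

    Returns ``(mesh, point_vectors, cell_scalars)``; region tags are restored
    as ``region_<id>`` (names are not stored in VTK).
    """
    with open(path) as f:
        tok = f.read().split()
    i = 0

    def seek(word):
        nonlocal i
        while tok[i] != word:
            i += 1

    seek("POINTS")
    n = int(tok[i + 1])
    i += 3
    nodes = np.array(tok[i : i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    seek("CELLS")
    m = int(tok[i + 1])
    i += 3
    cells = np.array(tok[i : i + 5 * m], dtype=int).reshape(m, 5)[:, 1:]
    point_vectors, cell_scalars = {}, {}
    j = i + 5 * m
    while j < len(tok):
        if tok[j] == "VECTORS":
            name = tok[j + 1]
            j += 3
            point_vectors[name] = np.array(tok[j : j + 3 * n], dtype=float).reshape(n, 3)
            j += 3 * n
        elif tok[j] == "SCALARS":
            name = tok[j + 1]
            j += 6  # SCALARS name type 1 LOOKUP_TABLE default
            cell_scalars[name] = np.array(tok[j : j + m], dtype=float)
            j += m
        else:
            j += 1
    rid = cell_scalars.pop("region_id", np.zeros(m))
    regions = np.array([f"region_{int(r)}" for r in rid])
    mesh = FEMesh(nodes=nodes, elements=cells, regions=regions)
    return mesh, point_vectors, cell_scalars


# ---------------------------------------------------------------------------
# Abaqus INP subset
# ---------------------------------------------------------------------------

# C3D4 element faces in Abaqus local numbering (1-based local nodes)
_C3D4_FACES = {1: (0, 1, 2), 2: (0, 3, 1), 3: (1, 3, 2), 4: (2, 3, 0)}


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_-]", "_", name)


def write_inp(mesh: FEMesh, path) -> None:
    """Write the INP subset: *NODE, *ELEMENT (C3D4 per region), *NSET, *ELSET, *SURFACE."""
    # map each facet triple to (element, face id) for surfaces
    face_lookup = {}
    for e, el in enumerate(mesh.elements):
        for fid, loc in _C3D4_FACES.items():
            key = tuple(sorted(el[list(loc)]))
            face_lookup[key] = (e, fid)
    with open(path, "w") as f:
        f.write("*HEADING\nsymphysim toy pelvis\n*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i}, {x:.16g}, {y:.16g}, {z:.16g}\n")
        for region in sorted(set(mesh.regions.tolist())):
            f.write(f"*ELEMENT, TYPE=C3D4, ELSET={_sanitize(region)}\n")
            for e in np.flatnonzero(mesh.regions == region):
                el = mesh.elements[e]
                f.write(f"{e+1}, {el[0]+1}, {el[1]+1}, {el[2]+1}, {el[3]+1}\n")
        for name, nset in mesh.node_sets.items():
            f.write(f"*NSET, NSET={_sanitize(name)}\n")
            ids = (np.asarray(nset) + 1).tolist()
            for k in range(0, len(ids), 12):
                f.write(", ".join(map(str, ids[k : k + 12])) + "\n")
        for name, eset in mesh.elem_sets.items():
            f.write(f"*ELSET, ELSET={_sanitize(name)}_set\n")
            ids = (np.asarray(eset) + 1).tolist()
            for k in range(0, len(ids), 12):
                f.write(", ".join(map(str, ids[k : k + 12])) + "\n")
        for name, facets in mesh.facet_sets.items():
            f.write(f"*SURFACE, TYPE=ELEMENT, NAME={_sanitize(name)}\n")
            for tri in facets:
                key = tuple(sorted(tri))
                if key not in face_lookup:
                    raise ValueError(f"facet {tri} of surface {name!r} matches no element face")
                e, fid = face_lookup[key]
                f.write(f"{e+1}, S{fid}\n")


def read_inp(path) -> FEMesh:
    """Read the INP subset written by :func:`write_inp`."""
    nodes, node_ids = [], {}
    elements, elem_ids, regions = [], {}, []
    node_sets, elem_sets, facet_sets = {}, {}, {}
    mode, current, region = None, None, None
    pending_surfaces: dict[str, list[tuple[int, int]]] = {}
    with open(path) as f:
        for raw in f:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                up = line.upper()
                if up.startswith("*NODE"):
                    mode = "node"
                elif up.startswith("*ELEMENT"):
                    mode = "element"
                    region = re.search(r"ELSET=([^,\s]+)", line, re.I).group(1)
                elif up.startswith("*NSET"):
                    mode = "nset"
                    current = re.search(r"NSET=([^,\s]+)", line, re.I).group(1)
                    node_sets[current] = []
                elif up.startswith("*ELSET"):
                    mode = "elset"
                    current = re.search(r"ELSET=([^,\s]+)", line, re.I).group(1)
                    elem_sets[current] = []
                elif up.startswith("*SURFACE"):
                    mode = "surface"
                    current = re.search(r"NAME=([^,\s]+)", line, re.I).group(1)
                    pending_surfaces[current] = []
                else:
                    mode = None
                continue
            parts = [pp.strip() for pp in line.split(",") if pp.strip()]
            if mode == "node":
                node_ids[int(parts[0])] = len(nodes)
                nodes.append([float(v) for v in parts[1:4]])
            elif mode == "element":
                elements.append((int(parts[0]), [node_ids[int(v)] for v in parts[1:5]], region))
            elif mode == "nset":
                node_sets[current].extend(node_ids[int(v)] for v in parts)
            elif mode == "elset":
                elem_sets[current].extend(int(v) for v in parts)  # file ids, remapped below
            elif mode == "surface":
                pending_surfaces[current].append((int(parts[0]), int(parts[1][1:])))
    # restore original element ordering (the writer groups by region)
    elements.sort(key=lambda t: t[0])
    regions = [t[2] for t in elements]
    elem_ids = {t[0]: i for i, t in enumerate(elements)}
    elements = np.asarray([t[1] for t in elements], dtype=int)
    elem_sets = {k: [elem_ids[i] for i in v] for k, v in elem_sets.items()}
    for name, refs in pending_surfaces.items():
        tris = [elements[elem_ids[e]][list(_C3D4_FACES[fid])] for e, fid in refs]
        facet_sets[name] = np.asarray(tris, dtype=int)
    return FEMesh(
        nodes=np.asarray(nodes),
        elements=elements,
        regions=np.asarray(regions),
        node_sets={k: np.asarray(v, dtype=int) for k, v in node_sets.items()},
        elem_sets={k: np.asarray(v, dtype=int) for k, v in elem_sets.items()},
        facet_sets=facet_sets,
    )


# ---------------------------------------------------------------------------
# density CSV
# ---------------------------------------------------------------------------


def write_density_csv(rho_ct: np.ndarray, path) -> None:
    """Write per-element calibration density as ``element_id,rho_ct``."""
    with open(path, "w") as f:
        f.write("element_id,rho_ct\n")
        for i, r in enumerate(np.asarray(rho_ct, dtype=float)):
            f.write(f"{i},{r:.16g}\n")


def read_density_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path)
    out = np.full(int(df["element_id"].max()) + 1, np.nan)
    out[df["element_id"].to_numpy()] = df["rho_ct"].to_numpy()
    return out
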