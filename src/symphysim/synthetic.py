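"""Parametric toy pelvis: geometry, density field and reference load cases.

The generator emulates the structures the analysis needs without any subject
data: two bone bodies (bent bars standing in for the hip bones) joined by a
slit-like interpubic disc block, a cortical-shell/cancellous-core density
contrast, one fixed and one spring-supported sacroiliac patch, an acetabular
loading patch and 27 named muscle attachment sites.  Everything downstream
(materials, muscle forces, FE solve, reporting) runs on its output.

Coordinates: x lateral (+ right), y vertical (+ up), z anterior-posterior;
the mid-sagittal plane is x = 0 and the geometry is mirror-symmetric about it
up to mesh tolerance.  Units mm and g/cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .loadcase import LoadCase, MuscleLoad, PointLoad, SpringSupport
from .mesh import FEMesh, MeshError
from .stance_forces import MUSCLE_NAMES, standing_muscle_forces

__all__ = [
    "PelvisToyParams",
    "DensityField",
    "generate_toy_pelvis",
    "generate_density",
    "reference_load_case",
    "HIP_REACTION_N",
    "SIJ_SPRING_STIFFNESS",
]

#: Hip-joint reaction components (N) at the single-leg-stance instant t=0.74 s.
HIP_REACTION_N = (852.0, 2052.0, -1042.0)

#: Physiological sacroiliac-joint spring stiffness, N/mm.
SIJ_SPRING_STIFFNESS = 4285.0

#: Attachment stations for the 27 tabulated muscles: (face, fraction), where
#: the fraction is axial (from the symphysis end) on arm faces and a height
#: fraction on the iliac-wing faces.
_MUSCLE_SITES = {
    "Adductor brevis": ("bottom", 0.08),
    "Adductor longus": ("bottom", 0.06),
    "Adductor magnus 1": ("bottom", 0.10),
    "Adductor magnus 2": ("bottom", 0.13),
    "Adductor magnus 3": ("bottom", 0.16),
    "Gracilis": ("bottom", 0.05),
    "Pectineus": ("top", 0.12),
    "Quadratus femoris": ("bottom", 0.22),
    "Biceps femoris - long head": ("bottom", 0.26),
    "Biceps femoris - short head": ("bottom", 0.28),
    "Semimembranosus": ("bottom", 0.24),
    "Semitendinosus": ("bottom", 0.25),
    "Rectus femoris": ("front", 0.40),
    "Sartorius": ("front", 0.45),
    "Tensor fasciae latae": ("front", 0.55),
    "Iliacus": ("top", 0.50),
    "Psoas major": ("top", 0.45),
    "Gluteus minimus 1": ("wing_lat", 0.15),
    "Gluteus minimus 2": ("wing_lat", 0.30),
    "Gluteus minimus 3": ("wing_lat", 0.45),
    "Gluteus medius 1": ("wing_lat", 0.40),
    "Gluteus medius 2": ("wing_lat", 0.60),
    "Gluteus medius 3": ("wing_lat", 0.80),
    "Gluteus maximus 1": ("wing_post", 0.35),
    "Gluteus maximus 2": ("wing_post", 0.60),
    "Gluteus maximus 3": ("wing_post", 0.85),
    "Piriformis": ("wing_post", 0.15),
}


@dataclass
class PelvisToyParams:
    """Parameters of the toy pelvis generator.

    Bone arms are bars of rectangular cross-section bent posteriorly by
    ``arc_angle``; the disc is a slit-like block between their medial faces.
    Mesh edge targets follow the study conditions for the real pelvis (5 mm
    global bone mesh, refined near the symphysis); the refined edge is kept at
    1.5 mm, a resolution appropriate for the smooth toy geometry.
    """

    arm_length: float = 60.0  # mm, each bone arm
    cross_section: float = 40.0  # mm, bar height (depth is 0.6x)
    disc_width: float = 4.0  # mm, symphysis gap (x extent of the disc)
    wing_height: float = 45.0  # mm, iliac-wing plate above the outer arm
    wing_start: float = 0.7  # wing footprint begins at this arm fraction
    arc_angle: float = 0.6  # rad, posterior bend of each arm
    coarse_edge: float = 5.0  # mm, global bone mesh size
    fine_edge: float = 1.5  # mm, near the symphysis and in the disc
    cortical_rho_ct: float = 1.1  # g/cm^3, shell calibration density
    cancellous_rho_ct: float = 0.25  # g/cm^3, core calibration density
    shell_thickness: float = 3.0  # mm, cortical shell depth
    noise_sd: float = 0.02  # g/cm^3, per-element density noise
    seed: int = 0

    def __post_init__(self):
        if min(self.arm_length, self.cross_section, self.disc_width) <= 0:
            raise ValueError("all lengths must be positive")
        if self.cortical_rho_ct <= self.cancellous_rho_ct:
            raise ValueError("cortical density must exceed cancellous density")
        if self.fine_edge > self.coarse_edge:
            raise ValueError("refined edge must not exceed the coarse edge")

    @property
    def depth(self) -> float:
        return 0.6 * self.cross_section


@dataclass
class DensityField:
    """Per-element calibration density rho_CT; NaN for disc elements."""

    rho_ct: np.ndarray
    provenance: dict

    def bone_values(self) -> np.ndarray:
        return self.rho_ct[np.isfinite(self.rho_ct)]


# ---------------------------------------------------------------------------
# structured tetrahedral grids
# ---------------------------------------------------------------------------


def _graded_axis(length: float, h0: float, h1: float) -> np.ndarray:
    """Monotone coordinates from 0 to length with spacing ramping h0 -> h1."""
    xs = [0.0]
    while xs[-1] < length - 1e-9:
        t = xs[-1] / length
        xs.append(xs[-1] + h0 + (h1 - h0) * t)
    a = np.asarray(xs)
    return a * (length / a[-1])


def _uniform_axis(length: float, h: float) -> np.ndarray:
    n = max(1, int(round(length / h)))
    return np.linspace(0.0, length, n + 1)


_CUBE_TETS = (  # Freudenthal/Kuhn decomposition, all positively oriented
    (0b000, 0b100, 0b110, 0b111),
    (0b000, 0b110, 0b010, 0b111),
    (0b000, 0b010, 0b011, 0b111),
    (0b000, 0b011, 0b001, 0b111),
    (0b000, 0b001, 0b101, 0b111),
    (0b000, 0b101, 0b100, 0b111),
)


def _box_tets(xs, ys, zs):
    """Structured tet mesh of a box; returns (nodes (n,3), tets (m,4))."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    cells = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                corner = {}
                for b in range(8):
                    di, dj, dk = (b >> 2) & 1, (b >> 1) & 1, b & 1
                    corner[b] = nid(i + di, j + dj, k + dk)
                for t in _CUBE_TETS:
                    cells.append([corner[v] for v in t])
    return nodes, np.asarray(cells, dtype=int)


def _face_nodes(nodes, axis, value, tol=1e-9):
    return np.flatnonzero(np.abs(nodes[:, axis] - value) < tol)


def _bend(nodes: np.ndarray, x0: float, length: float, theta: float, sign: float) -> np.ndarray:
    """Bend a bar extending from |x| = x0 outward by arc angle theta.

    The bar axis (local coordinate s = sign*x - x0 in [0, length]) is mapped
    onto a circular arc curving toward +z, with cross-sections rotated to stay
    normal to the arc.  theta = 0 is the identity (straight bar).
    """
    if abs(theta) < 1e-12:
        return nodes.copy()
    out = nodes.copy()
    s = sign * nodes[:, 0] - x0
    z = nodes[:, 2]
    R = length / theta
    phi = theta * s / length
    out[:, 0] = sign * (x0 + R * np.sin(phi) - z * np.sin(phi))
    out[:, 2] = R * (1.0 - np.cos(phi)) + z * np.cos(phi)
    return out


def _facets_on_nodes(mesh_elements: np.ndarray, region_mask: np.ndarray, node_set: np.ndarray):
    """Surface facets of a region whose three nodes all lie in ``node_set``."""
    from .mesh import surface_facets

    facets = surface_facets(mesh_elements, np.flatnonzero(region_mask))
    member = np.zeros(mesh_elements.max() + 1, dtype=bool)
    member[node_set] = True
    keep = member[facets].all(axis=1)
    return facets[keep]


# ---------------------------------------------------------------------------
# toy pelvis
# ---------------------------------------------------------------------------


def generate_toy_pelvis(params: PelvisToyParams | None = None) -> FEMesh:
    """Build the two-bone + disc toy pelvis with all named sets.

    The mesh is fully deterministic for given parameters (no randomness) and
    mirror-symmetric about x = 0.  Raises :class:`~symphysim.mesh.MeshError`
    with a parameter diagnostic if the requested discretization degenerates.
    """
    p = params or PelvisToyParams()
    h = p.cross_section
    d = p.depth
    w2 = p.disc_width / 2.0

    # disc block, refined everywhere
    fe = p.fine_edge
    dx = _uniform_axis(p.disc_width, min(fe, p.disc_width / 2.0))
    dy = _uniform_axis(h, fe)
    dz = _uniform_axis(d, fe)
    disc_nodes, disc_tets = _box_tets(dx - w2, dy - h / 2.0, dz - d / 2.0)

    # right bone: superior-pubic-ramus-like bar on [w2, w2+L] plus an
    # iliac-wing plate rising from the outer arm (where the gluteals attach
    # and which levers muscle forces about the SIJ)
    bx = _graded_axis(p.arm_length, p.fine_edge, p.coarse_edge) + w2
    cross_h = min(p.coarse_edge, h / 4.0)
    by = _uniform_axis(h, cross_h)
    bz = _uniform_axis(d, cross_h)
    arm_nodes, arm_tets = _box_tets(bx, by - h / 2.0, bz - d / 2.0)
    wing_x = bx[bx - w2 >= p.wing_start * p.arm_length - 1e-9]
    if p.wing_height > 0:
        if wing_x.size < 2:
            raise MeshError(
                f"wing footprint empty: wing_start={p.wing_start}, arm_length={p.arm_length}"
            )
        wy = h / 2.0 + _uniform_axis(p.wing_height, cross_h)
        wing_nodes, wing_tets = _box_tets(wing_x, wy, bz - d / 2.0)
        stacked = np.vstack([arm_nodes, wing_nodes])
        stacked_tets = np.vstack([arm_tets, wing_tets + len(arm_nodes)])
        # merge the coincident wing-base / arm-top nodes
        key = np.round(stacked, 6)
        _, first, inverse = np.unique(
            key, axis=0, return_index=True, return_inverse=True
        )
        bone_nodes = stacked[first]
        bone_tets = inverse[stacked_tets]
    else:
        bone_nodes, bone_tets = arm_nodes, arm_tets

    # geometric sets in the straight configuration
    s_axial = bone_nodes[:, 0] - w2
    y_c, z_c = bone_nodes[:, 1], bone_nodes[:, 2]
    right_med_face = _face_nodes(bone_nodes, 0, w2)  # symphysis side
    right_sij_face = _face_nodes(bone_nodes, 0, w2 + p.arm_length)
    bottom = _face_nodes(bone_nodes, 1, -h / 2.0)
    acet_mask = np.zeros(len(bone_nodes), dtype=bool)
    acet_mask[bottom] = True
    # the acetabulum is broad (~half the arm length) and sits nearer the SIJ
    # than the symphysis
    acet = np.flatnonzero(
        acet_mask & (s_axial >= 0.50 * p.arm_length) & (s_axial <= 0.85 * p.arm_length)
    )
    if acet.size == 0:
        raise MeshError(
            f"acetabular patch empty: arm_length={p.arm_length}, coarse_edge={p.coarse_edge}"
        )

    bone_right = _bend(bone_nodes, w2, p.arm_length, p.arc_angle, sign=+1.0)
    # left bone: mirror x -> -x; restore orientation by swapping two nodes
    bone_left = bone_right.copy()
    bone_left[:, 0] *= -1.0
    left_tets = bone_tets[:, [0, 2, 1, 3]]

    # assemble global numbering: [right bone | left bone | disc]
    nR = len(bone_right)
    nL = len(bone_left)
    nodes = np.vstack([bone_right, bone_left, disc_nodes])
    elements = np.vstack([bone_tets, left_tets + nR, disc_tets + nR + nL])
    regions = np.concatenate(
        [
            np.full(len(bone_tets), "bone_right"),
            np.full(len(left_tets), "bone_left"),
            np.full(len(disc_tets), "disc"),
        ]
    )

    node_sets = {
        "right_SIJ": right_sij_face,
        "left_SIJ": right_sij_face + nR,
        "right_acetabulum": acet,
        "symphysis_interface_right": _face_nodes(disc_nodes, 0, w2) + nR + nL,
        "symphysis_interface_left": _face_nodes(disc_nodes, 0, -w2) + nR + nL,
    }

    # 27 muscle attachment sites on the right (stance-side) bone surface.
    # Arm stations run from the symphysis end (s = 0, standing in for the
    # pubis) to the SIJ end (s = L); the gluteal group sits on the wing,
    # parameterized by height, mimicking the rough anatomical aspect of each
    # attachment (adductors near the pubis on the inferior face, iliopsoas
    # and anterior thigh muscles mid-arm, gluteals on the iliac wing).
    arm_level = y_c <= h / 2.0 + 1e-9
    wing_level = y_c > h / 2.0 + 1e-9
    faces = {
        "bottom": bottom,
        "top": np.flatnonzero(np.isclose(y_c, h / 2.0)),
        "front": np.flatnonzero(np.isclose(z_c, -d / 2.0) & arm_level),
        "back": np.flatnonzero(np.isclose(z_c, d / 2.0) & arm_level),
        "wing_lat": np.flatnonzero(np.isclose(z_c, -d / 2.0) & wing_level),
        "wing_post": np.flatnonzero(np.isclose(z_c, d / 2.0) & wing_level),
    }
    for name in MUSCLE_NAMES:
        face_name, frac = _MUSCLE_SITES[name]
        if face_name.startswith("wing") and p.wing_height <= 0:
            # degenerate wing: fall back to the outer arm's superior face
            face_name, frac = "top", p.wing_start + (1 - p.wing_start) * frac
        face = faces[face_name]
        if face_name.startswith("wing"):
            coord = (y_c[face] - h / 2.0) / p.wing_height
        else:
            coord = s_axial[face] / p.arm_length
        dist = np.abs(coord - frac)
        radius_c = max(
            1.5 * p.coarse_edge / p.arm_length, np.sort(dist)[min(2, dist.size - 1)] + 1e-9
        )
        sel = face[dist <= radius_c]
        node_sets[name] = np.asarray(sel, dtype=int)

    mesh = FEMesh(nodes=nodes, elements=elements, regions=regions, node_sets=node_sets)

    # master surface facets for the ties (bone faces at the symphysis)
    right_mask = regions == "bone_right"
    left_mask = regions == "bone_left"
    mesh.facet_sets["bone_right_symphysis_face"] = _facets_on_nodes(
        elements, right_mask, right_med_face
    )
    mesh.facet_sets["bone_left_symphysis_face"] = _facets_on_nodes(
        elements, left_mask, right_med_face + nR
    )
    mesh.elem_sets["hip_bones"] = mesh.region_elements("bone_left", "bone_right")
    mesh.elem_sets["pubic_symphysis"] = mesh.region_elements("disc")
    try:
        mesh.validate()
    except MeshError as exc:
        raise MeshError(f"toy pelvis meshing failed for params {asdict(p)}: {exc}") from exc
    return mesh


# ---------------------------------------------------------------------------
# density field
# ---------------------------------------------------------------------------


def _point_surface_distance(points: np.ndarray, tris: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Min distance from each point to a set of triangles (vectorized)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab, ac = b - a, c - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    det = np.maximum(d00 * d11 - d01 * d01, 1e-30)
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        P = points[lo : lo + chunk]  # (p, 3)
        ap = P[:, None, :] - a[None, :, :]  # (p, t, 3)
        e0 = np.einsum("ptj,tj->pt", ap, ab)
        e1 = np.einsum("ptj,tj->pt", ap, ac)
        v = (d11 * e0 - d01 * e1) / det
        w = (d00 * e1 - d01 * e0) / det
        v = np.clip(v, 0.0, None)
        w = np.clip(w, 0.0, None)
        s = v + w
        scale = np.where(s > 1.0, 1.0 / np.maximum(s, 1e-30), 1.0)
        v *= scale
        w *= scale
        closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        dist = np.linalg.norm(P[:, None, :] - closest, axis=2)
        out[lo : lo + chunk] = dist.min(axis=1)
    return out


def generate_density(
    mesh: FEMesh, params: PelvisToyParams | None = None, seed: int | None = None
) -> DensityField:
    """Cortical-shell / cancellous-core calibration-density field.

    Bone elements whose centroid lies within ``shell_thickness`` of their
    bone's free surface receive the cortical level, interior elements the
    cancellous level; seeded Gaussian noise is added and truncated at zero.
    Disc elements carry NaN (no bone density).
    """
    p = params or PelvisToyParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    centroids = mesh.nodes[mesh.elements].mean(axis=1)
    rho = np.full(mesh.n_elements, np.nan)
    half_min = min(p.cross_section, p.depth) / 2.0
    all_cortical = False
    if p.shell_thickness >= half_min:
        warnings.warn(
            f"shell thickness {p.shell_thickness} mm exceeds the half cross-section "
            f"{half_min} mm: the whole bone becomes cortical",
            stacklevel=2,
        )
        all_cortical = True
    for region in ("bone_left", "bone_right"):
        els = mesh.region_elements(region)
        if els.size == 0:
            continue
        if all_cortical:
            shell = np.ones(els.size, dtype=bool)
        else:
            tris = mesh.nodes[mesh.surface(region)]
            dist = _point_surface_distance(centroids[els], tris)
            shell = dist <= p.shell_thickness
        base = np.where(shell, p.cortical_rho_ct, p.cancellous_rho_ct)
        rho[els] = np.maximum(base + rng.normal(0.0, p.noise_sd, els.size), 0.0)
    return DensityField(
        rho_ct=rho,
        provenance={"params": asdict(p), "seed": int(p.seed if seed is None else seed)},
    )


# ---------------------------------------------------------------------------
# reference load cases
# ---------------------------------------------------------------------------


def acetabulum_reference_point(mesh: FEMesh, offset=(0.0, -10.0, 0.0)) -> np.ndarray:
    """Reference point at the center of the acetabular patch (offset inferior)."""
    patch = mesh.node_sets["right_acetabulum"]
    return mesh.nodes[patch].mean(axis=0) + np.asarray(offset, dtype=float)


def femur_head_point(mesh: FEMesh) -> np.ndarray:
    """Femoral head center below the acetabulum (anchor for insertion points)."""
    return acetabulum_reference_point(mesh, offset=(0.0, -30.0, 0.0))


#: Default muscle insertion points as offsets (mm) from the femoral head
#: center: gluteal/pelvitrochanteric group on the greater trochanter
#: (lateral-inferior), iliopsoas on the lesser trochanter (medial-inferior),
#: adductor group along the medial femoral shaft, hamstrings and long
#: bi-articular muscles near the knee.  Only the direction of pull matters
#: (printed force magnitudes are authoritative); all offsets are overridable
#: through ``muscle_targets``.
_MUSCLE_INSERTION_OFFSETS = {
    "Gluteus maximus 1": (38.0, -35.0, 8.0),
    "Gluteus maximus 2": (38.0, -40.0, 8.0),
    "Gluteus maximus 3": (38.0, -45.0, 8.0),
    "Gluteus medius 1": (40.0, -28.0, 0.0),
    "Gluteus medius 2": (40.0, -32.0, 0.0),
    "Gluteus medius 3": (40.0, -36.0, 0.0),
    "Gluteus minimus 1": (38.0, -25.0, -3.0),
    "Gluteus minimus 2": (38.0, -28.0, -3.0),
    "Gluteus minimus 3": (38.0, -31.0, -3.0),
    "Piriformis": (40.0, -22.0, 3.0),
    "Quadratus femoris": (30.0, -45.0, 5.0),
    "Tensor fasciae latae": (45.0, -70.0, 0.0),
    "Iliacus": (-5.0, -25.0, 0.0),
    "Psoas major": (-5.0, -25.0, 0.0),
    "Pectineus": (-5.0, -35.0, 0.0),
    "Adductor brevis": (-10.0, -45.0, 0.0),
    "Adductor longus": (-10.0, -55.0, 0.0),
    "Adductor magnus 1": (-12.0, -50.0, 0.0),
    "Adductor magnus 2": (-12.0, -60.0, 0.0),
    "Adductor magnus 3": (-12.0, -70.0, 0.0),
    "Gracilis": (-12.0, -90.0, 0.0),
    "Rectus femoris": (0.0, -75.0, -15.0),
    "Sartorius": (-12.0, -90.0, -10.0),
    "Biceps femoris - long head": (8.0, -90.0, 5.0),
    "Biceps femoris - short head": (8.0, -90.0, 5.0),
    "Semimembranosus": (-8.0, -90.0, 5.0),
    "Semitendinosus": (-8.0, -90.0, 5.0),
}


def reference_load_case(
    mesh: FEMesh,
    include_muscles: bool = False,
    hip_force: tuple = HIP_REACTION_N,
    sij_stiffness: float = SIJ_SPRING_STIFFNESS,
    muscle_targets: dict | None = None,
) -> LoadCase:
    """Build the packaged single-leg-stance load cases.

    Case 1 (``include_muscles=False``): only the hip-joint reaction force,
    applied at the right-acetabulum reference point via distributed coupling.
    Case 2 (``include_muscles=True``) adds the 27 tabulated muscle forces at
    their attachment sets, each directed from the attachment centroid toward
    a per-muscle insertion point (anatomical offsets from the femoral head by
    default); printed magnitudes are authoritative and zero rows are
    preserved.  In both cases the left SIJ is fully fixed and the right SIJ
    is spring-supported.
    """
    ref = acetabulum_reference_point(mesh)
    case = LoadCase(
        name="muscles" if include_muscles else "reaction_only",
        point_loads=[
            PointLoad(
                tuple(float(v) for v in ref),
                tuple(float(f) for f in hip_force),
                "right_acetabulum",
            )
        ],
        fixed_sets=["left_SIJ"],
        springs=[SpringSupport("right_SIJ", float(sij_stiffness))],
    )
    if include_muscles:
        targets = muscle_targets or {}
        head = femur_head_point(mesh)
        table = standing_muscle_forces()
        for _, row in table.iterrows():
            name = row["name"]
            patch = mesh.node_sets[name]
            centroid = mesh.nodes[patch].mean(axis=0)
            default_target = head + np.asarray(_MUSCLE_INSERTION_OFFSETS[name], dtype=float)
            target = np.asarray(targets.get(name, default_target), dtype=float)
            direction = target - centroid
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 0 else np.array([0.0, -1.0, 0.0])
            force = tuple(float(x) for x in row["force_N"] * direction)
            case.muscle_loads.append(MuscleLoad(name, force))
    case.validate_against(mesh)
    return case
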