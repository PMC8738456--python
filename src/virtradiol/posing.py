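"""Virtual patient positioning: pose every tissue from a skeleton pose.

The positioning pipeline is purely geometric (no tissue mechanics, gravity
deliberately ignored) and fully automatic, in five stages:

1. **Rigging** -- adapt a named template skeleton to the labelled bone
   meshes of the patient: each joint moves to the midpoint of the closest
   point pair between the bone meshes it connects.
2. **Volumetrisation** -- fill the skin with a body-centred-cubic (BCC)
   tetrahedral lattice; lattice vertices inside a bone mesh inherit that
   bone's label.
3. **Weighting** -- per-bone skinning weights are the steady state of the
   diffusion (Laplace) equation on the lattice's vertex graph, with the
   bone's own vertices clamped to 1 and all other bones' vertices to 0
   (harmonic weights; the discrete maximum principle keeps them in [0, 1]).
4. **Mapping** -- every tissue vertex is embedded in its containing
   tetrahedron with barycentric coordinates.
5. **Skinning** -- bone rigid transforms (composed down the joint
   hierarchy) deform the lattice by linear blending, and the barycentric
   embedding carries the deformation to all tissue meshes.

Deformation is applied as a displacement added to the rest geometry, so an
identity pose is a bit-exact no-op for every vertex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
import trimesh

__all__ = [
    "Joint",
    "Bone",
    "Skeleton",
    "Pose",
    "VolumetricCage",
    "WeightField",
    "TissueEmbedding",
    "fit_skeleton",
    "volumetrise",
    "harmonic_weights",
    "compute_weights",
    "embed_tissues",
    "bone_transforms",
    "skin_cage",
    "pose_tissues",
    "save_pose",
    "load_pose",
    "save_skeleton",
    "load_skeleton",
]


class PoseError(ValueError):
    """Invalid pose, skeleton, or positioning-stage input."""


@dataclass(frozen=True)
class Joint:
    name: str
    rest_position: np.ndarray  # mm
    parent: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "rest_position",
                           np.asarray(self.rest_position, dtype=float))


@dataclass(frozen=True)
class Bone:
    """A rigid segment between two joints, owning named bone-tissue meshes."""

    name: str
    joints: tuple[str, str]     # (proximal, distal)
    tissues: tuple[str, ...] = ()


@dataclass(frozen=True)
class Skeleton:
    joints: tuple[Joint, ...]
    bones: tuple[Bone, ...]

    def __post_init__(self):
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise PoseError("duplicate joint names")
        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1:
            raise PoseError(f"skeleton must have exactly one root, found {len(roots)}")
        by_name = set(names)
        for j in self.joints:
            if j.parent is not None and j.parent not in by_name:
                raise PoseError(f"joint {j.name}: unknown parent {j.parent}")
        for b in self.bones:
            for jn in b.joints:
                if jn not in by_name:
                    raise PoseError(f"bone {b.name}: unknown joint {jn}")
        # parent graph must be a tree (acyclic: walk to root from everywhere)
        parent = {j.name: j.parent for j in self.joints}
        for start in names:
            seen, cur = set(), start
            while cur is not None:
                if cur in seen:
                    raise PoseError(f"joint parent cycle through {cur}")
                seen.add(cur)
                cur = parent[cur]

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    @property
    def root(self) -> Joint:
        return next(j for j in self.joints if j.parent is None)

    def topo_order(self) -> list[Joint]:
        """Joints ordered parents-first."""
        out, placed = [], set()
        pending = list(self.joints)
        while pending:
            for j in list(pending):
                if j.parent is None or j.parent in placed:
                    out.append(j)
                    placed.add(j.name)
                    pending.remove(j)
        return out


IDENTITY_QUAT = (1.0, 0.0, 0.0, 0.0)  # (w, x, y, z)


@dataclass(frozen=True)
class Pose:
    """Per-joint local rotations (unit quaternions, w-first) + root shift."""

    rotations: dict[str, tuple[float, float, float, float]]
    root_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    standing: bool = True  # metadata only; gravity is not modelled

    def __post_init__(self):
        for name, q in self.rotations.items():
            norm = float(np.linalg.norm(q))
            if abs(norm - 1.0) > 1e-9:
                raise PoseError(f"quaternion for joint {name!r} not unit (|q|={norm})")
        object.__setattr__(self, "root_translation",
                           np.asarray(self.root_translation, dtype=float))

    @classmethod
    def identity(cls, skeleton: Skeleton) -> "Pose":
        return cls({j.name: IDENTITY_QUAT for j in skeleton.joints})


@dataclass
class VolumetricCage:
    """BCC tetrahedral lattice filling the skin, with bone-labelled vertices."""

    vertices: np.ndarray          # (N, 3) mm
    tetrahedra: np.ndarray        # (M, 4) int, positively oriented
    vertex_labels: list[str | None]  # bone name or None (free)
    spacing: float = 0.0

    def edges(self) -> np.ndarray:
        """Unique undirected vertex-pair edges of the tetrahedral mesh."""
        t = self.tetrahedra
        pairs = np.vstack([t[:, [a, b]] for a, b in
                           ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))])
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)


@dataclass(frozen=True)
class WeightField:
    """Vertices x bones skinning weights; rows sum to 1, entries in [0, 1]."""

    bone_names: tuple[str, ...]
    weights: np.ndarray  # (N, B)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-9) or np.any(w > 1 + 1e-9):
            raise PoseError("weights outside [0, 1]")
        rows = w.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise PoseError("weight rows must sum to 1")
        object.__setattr__(self, "weights", np.clip(w, 0.0, 1.0))


@dataclass(frozen=True)
class TissueEmbedding:
    """Barycentric anchoring of tissue meshes in the cage."""

    tet_index: dict[str, np.ndarray]      # tissue -> (n,) tet ids
    barycentric: dict[str, np.ndarray]    # tissue -> (n, 4), rows sum to 1
    rest_vertices: dict[str, np.ndarray]  # tissue -> (n, 3) rest positions
    n_cage_vertices: int = 0
    n_cage_tets: int = 0
    snapped: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage 1: rigging


def _closest_point_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point (Ericson's method).

    ``p`` broadcasts against ``tri[..., 0, :]``; returns the same shape.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    out = a + v[..., None] * ab + w[..., None] * ac        # interior face
    bc_pt = b + w_bc[..., None] * (c - b)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(on_bc[..., None], bc_pt, out)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(on_ac[..., None], a + w_ac[..., None] * ac, out)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(on_ab[..., None], a + v_ab[..., None] * ab, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], np.broadcast_to(c, out.shape), out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], np.broadcast_to(b, out.shape), out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], np.broadcast_to(a, out.shape), out)
    return out


def closest_point_on_mesh(points, mesh: trimesh.Trimesh, k: int = 32):
    """(closest surface points, distances) for query points on a mesh."""
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    k = min(k, len(mesh.faces))
    _, cand = cKDTree(mesh.triangles_center).query(points, k=k)
    cand = cand.reshape(len(points), k)
    tri = mesh.triangles.view(np.ndarray)[cand]            # (n, k, 3, 3)
    cp = _closest_point_triangles(points[:, None, :], tri)  # (n, k, 3)
    d2 = np.einsum("nkj,nkj->nk", cp - points[:, None, :], cp - points[:, None, :])
    j = d2.argmin(axis=1)
    rows = np.arange(len(points))
    return cp[rows, j], np.sqrt(d2[rows, j])


def _closest_pair(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh):
    """Approximate closest point pair between two surfaces.

    Seeded by the closest vertex pair, then refined by alternating exact
    surface projections (two Frank-Wolfe style sweeps are ample for convex
    bone-scale geometry).
    """
    from scipy.spatial import cKDTree

    dist, ib = cKDTree(mesh_b.vertices).query(mesh_a.vertices)
    ia = int(np.argmin(dist))
    pa = mesh_a.vertices[ia]
    for _ in range(2):
        (pb,), _ = closest_point_on_mesh(pa[None, :], mesh_b)
        (pa,), _ = closest_point_on_mesh(pb[None, :], mesh_a)
    return float(np.linalg.norm(pb - pa)), pa, pb


def fit_skeleton(template: Skeleton,
                 bone_meshes: dict[str, trimesh.Trimesh]) -> Skeleton:
    """Adapt the template skeleton to labelled bone meshes.

    Joints connecting two or more bones move to the midpoint of the closest
    point pair between the adjacent bone surfaces; joints with a single
    adjacent bone move to the mesh's extremal point along its principal
    axis, on the side nearest the template joint.
    """
    def bone_mesh(bone: Bone) -> trimesh.Trimesh:
        missing = [t for t in bone.tissues if t not in bone_meshes]
        if missing or not bone.tissues:
            raise PoseError(
                f"bone {bone.name!r} has no labelled mesh for: {missing or bone.tissues}"
            )
        meshes = [bone_meshes[t] for t in bone.tissues]
        return meshes[0] if len(meshes) == 1 else trimesh.util.concatenate(meshes)

    adjacency: dict[str, list[Bone]] = {j.name: [] for j in template.joints}
    for b in template.bones:
        for jn in b.joints:
            adjacency[jn].append(b)

    new_joints = []
    for j in template.joints:
        bones = adjacency[j.name]
        if len(bones) >= 2:
            best = (np.inf, j.rest_position)
            for i in range(len(bones)):
                for k in range(i + 1, len(bones)):
                    d, pa, pb = _closest_pair(bone_mesh(bones[i]), bone_mesh(bones[k]))
                    if d < best[0]:
                        best = (d, 0.5 * (np.asarray(pa) + np.asarray(pb)))
            pos = best[1]
        elif len(bones) == 1:
            mesh = bone_mesh(bones[0])
            centroid = mesh.vertices.mean(axis=0)
            centred = mesh.vertices - centroid
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            axis = vt[0]
            proj = centred @ axis
            sign = 1.0 if float((j.rest_position - centroid) @ axis) >= 0 else -1.0
            extent = proj.max() if sign > 0 else -proj.min()
            pos = centroid + sign * extent * axis
        else:
            pos = j.rest_position
        new_joints.append(Joint(j.name, pos, j.parent))
    return Skeleton(tuple(new_joints), template.bones)


# ---------------------------------------------------------------------------
# Stage 2: volumetrisation

# edges of the square face shared by two adjacent BCC cell centres
_FACE_LOOP = ((0, 1), (1, 3), (3, 2), (2, 0))


def _bcc_lattice(bounds, spacing):
    """Corner + centre points of a BCC lattice covering ``bounds``."""
    lo, hi = bounds
    counts = np.ceil((hi - lo) / spacing).astype(int) + 2
    origin = lo - spacing
    axes = [origin[a] + spacing * np.arange(counts[a] + 1) for a in range(3)]
    corners = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    shape = corners.shape[:3]
    centers = corners[:-1, :-1, :-1] + spacing / 2.0
    return corners, centers, shape


def volumetrise(skin_mesh: trimesh.Trimesh,
                bone_meshes: dict[str, trimesh.Trimesh],
                lattice_spacing: float) -> VolumetricCage:
    """Fill the skin with BCC tetrahedra and label bone-interior vertices.

    Tetrahedra connect two adjacent cell centres with each edge of their
    shared lattice face (the standard BCC tet split); only tetrahedra whose
    four vertices all lie inside the skin are kept.  Every bone must label
    at least one kept vertex, otherwise the spacing is too coarse.
    """
    if not lattice_spacing > 0:
        raise PoseError("lattice spacing must be positive")
    corners, centers, cshape = _bcc_lattice(skin_mesh.bounds, lattice_spacing)
    corner_flat = corners.reshape(-1, 3)
    center_flat = centers.reshape(-1, 3)
    n_corner = corner_flat.shape[0]
    all_pts = np.vstack([corner_flat, center_flat])

    def cidx(i, j, k):  # corner index grids -> flat ids
        return (i * cshape[1] + j) * cshape[2] + k

    def zidx(i, j, k):  # centre index grids -> flat ids (offset by n_corner)
        nz = np.array(cshape) - 1
        return n_corner + (i * nz[1] + j) * nz[2] + k

    tets = []
    nz = np.array(cshape) - 1
    for axis in range(3):
        span = nz.copy()
        span[axis] -= 1
        if np.any(span <= 0):
            continue
        i, j, k = np.meshgrid(*[np.arange(s) for s in span], indexing="ij")
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        step = np.zeros(3, dtype=int)
        step[axis] = 1
        c1 = zidx(i, j, k)
        c2 = zidx(i + step[0], j + step[1], k + step[2])
        # shared face corners: offset one along `axis`, spanning the other two
        o1, o2 = [a for a in range(3) if a != axis]
        base = [i + step[0], j + step[1], k + step[2]]
        quad = []
        for d1 in (0, 1):
            for d2 in (0, 1):
                ijk = [b.copy() for b in base]
                ijk[o1] = ijk[o1] + d1
                ijk[o2] = ijk[o2] + d2
                quad.append(cidx(*ijk))
        for a, b in _FACE_LOOP:
            tets.append(np.stack([c1, c2, quad[a], quad[b]], axis=1))
    tets = np.vstack(tets)

    from .projector import points_inside

    # containment test batched once over all candidate lattice points
    inside = points_inside(all_pts, skin_mesh)
    keep = inside[tets].all(axis=1)
    tets = tets[keep]
    if tets.size == 0:
        raise PoseError("lattice spacing too coarse: no tetrahedron fits the skin")

    used = np.unique(tets)
    remap = -np.ones(all_pts.shape[0], dtype=int)
    remap[used] = np.arange(used.size)
    vertices = all_pts[used]
    tets = remap[tets]

    # enforce positive orientation
    a, b, c, d = (vertices[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    labels: list[str | None] = [None] * vertices.shape[0]
    for bone_name, mesh in bone_meshes.items():
        hit = points_inside(vertices, mesh)
        for vi in np.nonzero(hit)[0]:
            labels[vi] = bone_name
    missing = [bn for bn in bone_meshes
               if not any(lb == bn for lb in labels)]
    if missing:
        raise PoseError(
            f"lattice spacing {lattice_spacing} mm too coarse to label bones: {missing}"
        )
    return VolumetricCage(vertices, tets, labels, spacing=lattice_spacing)


# ---------------------------------------------------------------------------
# Stage 3: harmonic weighting


def harmonic_weights(n_vertices: int, edges: np.ndarray,
                     labels: list[str | None],
                     bone_names: list[str]) -> WeightField:
    """Steady-state diffusion weights on an arbitrary vertex-edge graph.

    For each bone b the discrete Laplace equation (uniform combinatorial
    edge weights) is solved with Dirichlet data w=1 on vertices labelled b
    and w=0 on vertices labelled any other bone.  Rows are then normalised
    to sum to 1.
    """
    edges = np.asarray(edges, dtype=int)
    fixed = np.array([lb is not None for lb in labels])
    free = ~fixed
    adj = sp.coo_matrix(
        (np.ones(len(edges) * 2),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n_vertices, n_vertices),
    ).tocsr()

    n_comp, comp = csgraph.connected_components(adj, directed=False)
    for c in range(n_comp):
        members = comp == c
        if not fixed[members].any():
            ids = np.nonzero(members)[0]
            raise PoseError(
                f"free component of {ids.size} vertices (e.g. vertex {ids[0]}) "
                "touches no labelled bone vertex"
            )

    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sp.diags(deg) - adj
    w = np.zeros((n_vertices, len(bone_names)))
    free_ids = np.nonzero(free)[0]
    if free_ids.size:
        lap_ff = lap[free_ids][:, free_ids].tocsc()
        solve = spla.factorized(lap_ff)
    for bi, bone in enumerate(bone_names):
        boundary = np.array([1.0 if lb == bone else 0.0 for lb in labels])
        w[fixed, bi] = boundary[fixed]
        if free_ids.size:
            rhs = -(lap[free_ids][:, fixed] @ boundary[fixed])
            w[free_ids, bi] = solve(rhs)
    w = np.clip(w, 0.0, 1.0)
    rows = w.sum(axis=1)
    if np.any(rows <= 0):
        raise PoseError("vertex with all-zero weights; graph not anchored")
    return WeightField(tuple(bone_names), w / rows[:, None])


def compute_weights(cage: VolumetricCage) -> WeightField:
    """Harmonic weights of the cage's bones on its tetrahedral vertex graph."""
    bone_names = sorted({lb for lb in cage.vertex_labels if lb is not None})
    if not bone_names:
        raise PoseError("cage has no labelled bone vertices")
    return harmonic_weights(len(cage.vertices), cage.edges(),
                            cage.vertex_labels, bone_names)


# ---------------------------------------------------------------------------
# Stage 4: barycentric mapping


def _tet_barycentric(points, vertices, tets):
    """Barycentric coords of each point in each candidate tet (vectorised)."""
    a = vertices[tets[:, 0]]
    m = np.stack([vertices[tets[:, 1]] - a,
                  vertices[tets[:, 2]] - a,
                  vertices[tets[:, 3]] - a], axis=-1)  # (M, 3, 3)
    local = np.linalg.solve(m, (points - a)[..., None])[..., 0]  # (M, 3)
    return np.concatenate([1 - local.sum(axis=-1, keepdims=True), local], axis=-1)


def embed_tissues(tissues: dict[str, trimesh.Trimesh],
                  cage: VolumetricCage) -> TissueEmbedding:
    """Anchor every tissue vertex in its containing tetrahedron.

    Vertices outside all tetrahedra (the skin shell the conservative lattice
    does not cover) are assigned the least-violating nearby tetrahedron with
    its exact affine-extension coordinates (possibly negative, still summing
    to 1): the linear extrapolation keeps rigid and affine cage motions
    exact for every vertex.  The per-tissue count of such vertices is
    recorded in ``snapped``.
    """
    from scipy.spatial import cKDTree

    centroids = cage.vertices[cage.tetrahedra].mean(axis=1)
    tree = cKDTree(centroids)
    tet_index, barycentric, rest, snapped = {}, {}, {}, {}
    k = min(48, len(cage.tetrahedra))
    for name, mesh in tissues.items():
        pts = np.asarray(mesh.vertices, dtype=float)
        n = pts.shape[0]
        idx = np.full(n, -1, dtype=int)
        bary = np.zeros((n, 4))
        _, cand = tree.query(pts, k=k)
        cand = np.asarray(cand).reshape(n, -1)
        best_viol = np.full(n, np.inf)
        best_idx = np.zeros(n, dtype=int)
        best_bary = np.zeros((n, 4))
        for ci in range(cand.shape[1]):
            tids = cand[:, ci]
            b = _tet_barycentric(pts, cage.vertices, cage.tetrahedra[tids])
            viol = np.maximum(-b.min(axis=1), 0.0)
            inside = (b.min(axis=1) >= -1e-6) & (idx < 0)
            idx[inside] = tids[inside]
            bary[inside] = b[inside]
            better = viol < best_viol
            best_viol[better] = viol[better]
            best_idx[better] = tids[better]
            best_bary[better] = b[better]
        missing = idx < 0
        if np.any(missing):
            idx[missing] = best_idx[missing]
            bary[missing] = best_bary[missing]
        tet_index[name] = idx
        barycentric[name] = bary
        rest[name] = pts.copy()
        snapped[name] = int(missing.sum())
    return TissueEmbedding(tet_index, barycentric, rest,
                           n_cage_vertices=len(cage.vertices),
                           n_cage_tets=len(cage.tetrahedra), snapped=snapped)


# ---------------------------------------------------------------------------
# Stage 5: skinning


def _quat_matrix(q):
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def bone_transforms(skeleton: Skeleton, pose: Pose) -> dict[str, np.ndarray]:
    """Rigid 4x4 world transform per bone, composed down the joint hierarchy.

    Each joint rotates its subtree about its own rest position; a bone moves
    rigidly with its proximal joint.  The identity pose yields exact
    identity matrices.
    """
    missing = [j.name for j in skeleton.joints if j.name not in pose.rotations]
    if missing:
        raise PoseError(f"pose missing joints: {missing}")
    world: dict[str, np.ndarray] = {}
    for j in skeleton.topo_order():
        local = np.eye(4)
        q = pose.rotations[j.name]
        if tuple(q) != IDENTITY_QUAT:
            r = _quat_matrix(q)
            local[:3, :3] = r
            local[:3, 3] = j.rest_position - r @ j.rest_position
        if j.parent is None:
            t = np.eye(4)
            if np.any(pose.root_translation != 0):
                t[:3, 3] = pose.root_translation
            world[j.name] = t @ local
        else:
            world[j.name] = world[j.parent] @ local
    return {b.name: world[b.joints[0]] for b in skeleton.bones}


def skin_cage(cage: VolumetricCage, weights: WeightField,
              skeleton: Skeleton, pose: Pose) -> np.ndarray:
    """Linear-blend-skinned cage vertices: v' = v + sum_b w_vb (T_b v - v).

    The displacement form makes identity bone transforms a bit-exact no-op.
    """
    transforms = bone_transforms(skeleton, pose)
    missing = [b for b in weights.bone_names if b not in transforms]
    if missing:
        raise PoseError(f"weight field references unknown bones: {missing}")
    v = cage.vertices
    out = v.copy()
    for bi, bone in enumerate(weights.bone_names):
        t = transforms[bone]
        if np.array_equal(t, np.eye(4)):
            continue
        moved = v @ t[:3, :3].T + t[:3, 3]
        out = out + weights.weights[:, bi:bi + 1] * (moved - v)
    return out


def pose_tissues(tissues: dict[str, trimesh.Trimesh],
                 embedding: TissueEmbedding,
                 cage: VolumetricCage,
                 deformed_vertices: np.ndarray) -> dict[str, trimesh.Trimesh]:
    """Carry the cage deformation to the tissue meshes.

    Each tissue vertex moves by the barycentric blend of its tetrahedron's
    vertex displacements; connectivity is untouched.  An undeformed cage
    returns bit-identical tissues.
    """
    deformed_vertices = np.asarray(deformed_vertices, dtype=float)
    if deformed_vertices.shape != cage.vertices.shape or \
            embedding.n_cage_vertices != len(cage.vertices) or \
            embedding.n_cage_tets != len(cage.tetrahedra):
        raise PoseError("embedding/cage topology mismatch")
    delta = deformed_vertices - cage.vertices
    out = {}
    for name, mesh in tissues.items():
        if name not in embedding.tet_index:
            raise PoseError(f"tissue {name!r} not present in embedding")
        tets = cage.tetrahedra[embedding.tet_index[name]]     # (n, 4)
        bary = embedding.barycentric[name]                    # (n, 4)
        disp = np.einsum("nk,nkj->nj", bary, delta[tets])
        new_v = embedding.rest_vertices[name] + disp
        out[name] = trimesh.Trimesh(vertices=new_v, faces=mesh.faces.copy(),
                                    process=False)
    return out


# ---------------------------------------------------------------------------
# Pose / skeleton serialisation (JSON)


def save_pose(pose: Pose, stream) -> None:
    doc = {
        "format": "virtradiol-pose",
        "version": 1,
        "standing": pose.standing,
        "root_translation_mm": [float(x) for x in pose.root_translation],
        "joints": {name: [float(c) for c in q]
                   for name, q in sorted(pose.rotations.items())},
    }
    text = json.dumps(doc, indent=2) + "\n"
    if hasattr(stream, "write"):
        stream.write(text)
    else:
        with open(stream, "w") as fh:
            fh.write(text)


def load_pose(stream, skeleton: Skeleton | None = None) -> Pose:
    if hasattr(stream, "read"):
        doc = json.load(stream)
    else:
        with open(stream) as fh:
            doc = json.load(fh)
    if doc.get("format") != "virtradiol-pose":
        raise PoseError("not a pose file (missing format tag)")
    rotations = {name: tuple(float(c) for c in q)
                 for name, q in doc["joints"].items()}
    if skeleton is not None:
        known = {j.name for j in skeleton.joints}
        unknown = sorted(set(rotations) - known)
        if unknown:
            raise PoseError(f"pose file names unknown joints: {unknown}")
        for j in known - set(rotations):
            rotations[j] = IDENTITY_QUAT
    return Pose(rotations,
                np.asarray(doc.get("root_translation_mm", [0, 0, 0]), dtype=float),
                standing=bool(doc.get("standing", True)))


def save_skeleton(skeleton: Skeleton, stream) -> None:
    doc = {
        "format": "virtradiol-skeleton",
        "version": 1,
        "joints": [
            {"name": j.name, "position_mm": [float(x) for x in j.rest_position],
             "parent": j.parent}
            for j in skeleton.joints
        ],
        "bones": [
            {"name": b.name, "joints": list(b.joints), "tissues": list(b.tissues)}
            for b in skeleton.bones
        ],
    }
    text = json.dumps(doc, indent=2) + "\n"
    if hasattr(stream, "write"):
        stream.write(text)
    else:
        with open(stream, "w") as fh:
            fh.write(text)


def load_skeleton(stream) -> Skeleton:
    if hasattr(stream, "read"):
        doc = json.load(stream)
    else:
        with open(stream) as fh:
            doc = json.load(fh)
    if doc.get("format") != "virtradiol-skeleton":
        raise PoseError("not a skeleton file (missing format tag)")
    joints = tuple(Joint(j["name"], np.asarray(j["position_mm"], dtype=float),
                         j.get("parent")) for j in doc["joints"])
    bones = tuple(Bone(b["name"], tuple(b["joints"]), tuple(b.get("tissues", ())))
                  for b in doc["bones"])
    return Skeleton(joints, bones)
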