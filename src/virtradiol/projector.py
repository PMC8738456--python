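"""Deterministic radiograph formation: L-buffer path lengths + Beer-Lambert.

The projector computes, for every detector pixel, the length of the ray
segment inside each closed tissue mesh (the *L-buffer*: the sum of signed
intersection distances sign(d . n) * t over all ray/triangle hits of a
watertight, outward-oriented mesh equals the interior path length), resolves
declared tissue containment (an inner mesh displaces its parent's material),
and attenuates each spectrum bin by the Beer-Lambert law

    I(p) = sum_i N(E_i) * E_i * exp(-sum_m mu_m(E_i) * L_m(p)).

The image value is energy fluence (keV * photons per pixel); the cassette is
an ideal receptor with no response curve.  Scatter and focal-spot blur are
not modelled -- the simulation is a pure ray-cast.  Quantum noise can be
mimicked after the fact with :func:`add_poisson_noise`, the deterministic
model's surrogate for the mAs setting.

Geometry is in mm; path lengths convert to cm at the attenuation boundary
(mu is conventionally cm^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .geometry import AcquisitionGeometry, collimator_mask, generate_rays
from .materials import (
    AttenuationTable,
    Material,
    hounsfield_to_material,
    linear_attenuation,
)
from .spectrum import Spectrum, total_energy_fluence

__all__ = [
    "SceneTissue",
    "RadiographImage",
    "validate_scene",
    "ray_path_length",
    "ray_path_lengths",
    "resolve_nesting",
    "simulate_radiograph",
    "add_poisson_noise",
]

log = logging.getLogger(__name__)

MM_PER_CM = 10.0
_GRAZE_TOL = 1e-12   # |d . n| below this: grazing hit, discarded
_BARY_TOL = 1e-10    # barycentric slack at triangle borders
_JITTERS_MM = (1e-9, 1e-6, 1e-3)  # origin offsets for degenerate re-casts


class SceneError(ValueError):
    """Invalid scene: bad mesh, unknown parent, or cyclic containment."""


@dataclass
class SceneTissue:
    """One closed tissue mesh with its material and display/containment state."""

    name: str
    mesh: trimesh.Trimesh
    material: Material
    visible: bool = True
    parent: str | None = None     # containing tissue (inner displaces outer)
    hu_override: float | None = None

    def effective_material(self) -> Material:
        """Material used for attenuation, honouring any HU override."""
        if self.hu_override is not None:
            mat = hounsfield_to_material(self.hu_override)
            return Material(self.name, mat.mass_fractions, mat.density,
                            mat.source_descriptor)
        return self.material


@dataclass(frozen=True)
class RadiographImage:
    """Energy-fluence image plus acquisition provenance."""

    pixels: np.ndarray               # (rows, cols), keV * photons, >= 0
    geometry: AcquisitionGeometry | None = None
    spectrum: Spectrum | None = None
    noisy: bool = False              # Poisson fluctuations may top the cap

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if np.any(px < 0):
            raise ValueError("radiograph pixels must be non-negative")
        if self.spectrum is not None and not self.noisy:
            cap = total_energy_fluence(self.spectrum)
            if np.any(px > cap * (1 + 1e-6)):
                raise ValueError("pixel exceeds open-field energy fluence")
        object.__setattr__(self, "pixels", px)


def check_mesh(mesh: trimesh.Trimesh, name: str = "mesh") -> None:
    """Reject meshes the L-buffer cannot handle (open or inconsistent)."""
    if not mesh.is_watertight:
        raise SceneError(f"{name}: mesh is not watertight")
    if not mesh.is_winding_consistent:
        raise SceneError(f"{name}: mesh winding is not consistent")
    if mesh.volume <= 0:
        raise SceneError(f"{name}: mesh is inward-oriented (negative volume)")


def validate_scene(scene: list[SceneTissue]) -> None:
    """Check mesh closedness and the containment graph once, up front."""
    names = [t.name for t in scene]
    if len(set(names)) != len(names):
        raise SceneError("duplicate tissue names in scene")
    by_name = {t.name: t for t in scene}
    for t in scene:
        check_mesh(t.mesh, t.name)
        if t.parent is not None and t.parent not in by_name:
            raise SceneError(f"{t.name}: unknown parent tissue {t.parent!r}")
    for t in scene:
        seen, cur = {t.name}, t.parent
        while cur is not None:
            if cur in seen:
                raise SceneError(
                    f"cyclic containment: {' -> '.join([*seen, cur])}"
                )
            seen.add(cur)
            cur = by_name[cur].parent


# ---------------------------------------------------------------------------
# L-buffer ray casting


def _signed_hits(origins, directions, tri, normals, pair_budget=4_000_000):
    """Sum of sign(d.n)*t and signed hit parity for each ray, vectorised.

    ``tri``: (T, 3, 3) triangle vertices; ``normals``: (T, 3) outward units.
    Returns (signed_length_mm, parity) arrays of shape (R,).  Moeller-
    Trumbore evaluated in chunks so the R x T working set stays bounded.
    """
    r_total = origins.shape[0]
    t_total = tri.shape[0]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    length = np.zeros(r_total)
    parity = np.zeros(r_total, dtype=np.int64)
    chunk = max(1, int(pair_budget // max(t_total, 1)))
    for start in range(0, r_total, chunk):
        sl = slice(start, min(start + chunk, r_total))
        o = origins[sl]                      # (R, 3)
        d = directions[sl]                   # (R, 3)
        pvec = np.cross(d[:, None, :], e2[None, :, :])      # (R, T, 3)
        det = np.einsum("tk,rtk->rt", e1, pvec)
        cos = np.einsum("rk,tk->rt", d, normals)            # d . n (unit n)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = 1.0 / det
            tvec = o[:, None, :] - v0[None, :, :]
            u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv_det
            qvec = np.cross(tvec, e1[None, :, :])
            v = np.einsum("rk,rtk->rt", d, qvec) * inv_det
            t = np.einsum("tk,rtk->rt", e2, qvec) * inv_det
            w = 1.0 - u - v
            inner = np.minimum(np.minimum(u, v), w)
            usable = (np.abs(cos) >= _GRAZE_TOL) & (np.abs(det) > 0) & (t > 0)
            # strict interior hits count; hits in the border band around an
            # edge/vertex could be double-counted by adjacent triangles, so
            # the whole ray is flagged degenerate and re-cast with jitter
            hit = usable & (inner > _BARY_TOL)
            border = usable & (np.abs(inner) <= _BARY_TOL)
        sign = np.where(cos > 0, 1.0, -1.0)
        contrib = np.where(hit, sign * t, 0.0)
        length[sl] = contrib.sum(axis=1)
        parity[sl] = np.where(hit, sign, 0).sum(axis=1).astype(np.int64)
        parity[sl][border.any(axis=1)] = np.iinfo(np.int64).min // 2
    return length, parity


def _aabb_may_hit(origins, directions, bounds):
    """Slab test: which rays can intersect the axis-aligned box ``bounds``."""
    lo, hi = bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / directions
        t0 = (lo[None, :] - origins) * inv
        t1 = (hi[None, :] - origins) * inv
    tmin = np.nanmax(np.minimum(t0, t1), axis=1)
    tmax = np.nanmin(np.maximum(t0, t1), axis=1)
    # rays parallel to an axis inside the slab give +-inf, handled by nan ops
    inside = np.all((origins >= lo) & (origins <= hi), axis=1)
    return inside | ((tmax >= np.maximum(tmin, 0.0)) & (tmin <= tmax))


def ray_path_lengths(origins, directions, mesh: trimesh.Trimesh) -> np.ndarray:
    """Interior path length (cm) of each ray through a closed mesh.

    Implements the L-buffer: accumulate sign(d . n) * t over every
    ray/triangle intersection; for a watertight outward-oriented surface the
    sum is the chord length inside the mesh.  Rays that graze a face or pass
    exactly through an edge/vertex can produce an unbalanced signed hit
    count; those rays are re-cast with a slightly offset origin.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if origins.shape[0] == 1 and directions.shape[0] > 1:
        origins = np.broadcast_to(origins, directions.shape).copy()
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)

    tri = mesh.triangles.view(np.ndarray)
    normals = mesh.face_normals.view(np.ndarray)
    out = np.zeros(origins.shape[0])

    candidates = _aabb_may_hit(origins, directions, mesh.bounds)
    idx = np.nonzero(candidates)[0]
    if idx.size == 0:
        return out / MM_PER_CM

    length, parity = _signed_hits(origins[idx], directions[idx], tri, normals)
    bad = (parity != 0) | (length < -1e-9)
    for jitter in _JITTERS_MM:
        if not np.any(bad):
            break
        sub = idx[bad]
        # offset origin perpendicular to the ray to slide off the edge/vertex
        d = directions[sub]
        perp = np.cross(d, [0.61803398875, 0.5698402909, 0.5227232255])
        small = np.linalg.norm(perp, axis=1) < 1e-6
        perp[small] = np.cross(d[small], [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp, axis=1, keepdims=True)
        l2, p2 = _signed_hits(origins[sub] + jitter * perp, d, tri, normals)
        length[bad], parity[bad] = l2, p2
        bad = (parity != 0) | (length < -1e-9)
    if np.any(bad):
        log.warning("%d rays remained degenerate after jitter; clamped", int(bad.sum()))
    out[idx] = np.clip(length, 0.0, None)
    return out / MM_PER_CM


def points_inside(points, mesh: trimesh.Trimesh) -> np.ndarray:
    """Boolean mask of points strictly inside a closed mesh.

    Casts one ray per point along a fixed irrational direction and counts
    signed crossings with the same kernel as the path-length L-buffer: the
    signed count ahead of an interior point is +1, of an exterior point 0.
    Degenerate rays (edge/vertex/grazing hits) are re-cast with a nudged
    direction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles.view(np.ndarray)
    normals = mesh.face_normals.view(np.ndarray)
    out = np.zeros(points.shape[0], dtype=bool)

    base_dir = np.array([0.57735026919, 0.57735026919, 0.57735026919])
    dirs = np.broadcast_to(base_dir, points.shape).copy()
    cand = _aabb_may_hit(points, dirs, mesh.bounds)
    idx = np.nonzero(cand)[0]
    if idx.size == 0:
        return out
    sub_pts = points[idx]
    parity = np.full(idx.size, np.iinfo(np.int64).min // 2, dtype=np.int64)
    rng_dirs = (
        base_dir,
        np.array([0.26726124191, 0.53452248382, 0.80178372573]),
        np.array([0.09853292781, 0.69915362239, 0.70814570723]),
    )
    for d in rng_dirs:
        bad = (parity < 0) | (parity > 1)
        if not np.any(bad):
            break
        dd = np.broadcast_to(d, (int(bad.sum()), 3))
        _, p = _signed_hits(sub_pts[bad], dd, tri, normals)
        parity[bad] = p
    out[idx] = parity == 1
    return out


def ray_path_length(origin, direction, mesh: trimesh.Trimesh) -> float:
    """Single-ray convenience wrapper around :func:`ray_path_lengths` (cm)."""
    return float(ray_path_lengths(np.asarray(origin)[None, :],
                                  np.asarray(direction)[None, :], mesh)[0])


# ---------------------------------------------------------------------------
# Containment resolution and image formation


def _material_key(material: Material):
    return (tuple(sorted(material.mass_fractions.items())), material.density)


def resolve_nesting(
    path_lengths: dict[str, np.ndarray],
    scene: list[SceneTissue],
) -> dict[object, tuple[Material, np.ndarray]]:
    """Aggregate per-tissue chords into per-material effective lengths (cm).

    A tissue with a declared parent displaces the parent's material: its
    chord is subtracted from the parent's before lengths of tissues sharing
    a material are summed.  Hidden tissues must already be absent from
    ``path_lengths``; a hidden inner tissue therefore leaves the parent
    chord whole.  Negative lengths after subtraction (inner mesh poking out
    of its parent) are clamped to zero with a warning.
    """
    tissues = {t.name: t for t in scene}
    effective = {name: np.array(L, dtype=float, copy=True)
                 for name, L in path_lengths.items()}
    for name in path_lengths:
        parent = tissues[name].parent
        if parent is not None and parent in effective:
            effective[parent] = effective[parent] - path_lengths[name]
    clamped = 0
    out: dict[object, tuple[Material, np.ndarray]] = {}
    for name, L in effective.items():
        neg = L < 0
        if np.any(neg):
            clamped += int(np.count_nonzero(neg))
            L = np.clip(L, 0.0, None)
        mat = tissues[name].effective_material()
        key = _material_key(mat)
        if key in out:
            out[key] = (out[key][0], out[key][1] + L)
        else:
            out[key] = (mat, L)
    if clamped:
        log.warning("clamped %d negative effective path lengths to 0", clamped)
    return out


def simulate_radiograph(
    scene: list[SceneTissue],
    geometry: AcquisitionGeometry,
    spectrum: Spectrum,
    table: AttenuationTable,
) -> RadiographImage:
    """Polychromatic Beer-Lambert projection of the scene."""
    validate_scene(scene)
    visible = [t for t in scene if t.visible]
    # fail fast on spectrum/table span mismatch, before any ray is cast
    materials_used = [t.effective_material() for t in visible] or []
    for mat in materials_used:
        linear_attenuation(mat, spectrum.energies_kev, table)

    focus, dirs = generate_rays(geometry)
    mask = collimator_mask(geometry).astype(bool)
    rows, cols = mask.shape
    flat_dirs = dirs.reshape(-1, 3)
    active = mask.reshape(-1)

    lengths: dict[str, np.ndarray] = {}
    for t in visible:
        L = np.zeros(rows * cols)
        if np.any(active):
            L[active] = ray_path_lengths(focus[None, :], flat_dirs[active], t.mesh)
        lengths[t.name] = L

    per_material = resolve_nesting(lengths, visible)
    e = spectrum.energies_kev
    weights = spectrum.counts * e                       # N_i * E_i per bin
    attn = np.zeros((len(e), rows * cols))
    for mat, L in per_material.values():
        mu = linear_attenuation(mat, e, table)          # (bins,), cm^-1
        attn += np.outer(mu, L)
    pixels = weights @ np.exp(-attn)                    # (rows*cols,)
    pixels = np.where(active, pixels, 0.0).reshape(rows, cols)
    return RadiographImage(pixels=pixels, geometry=geometry, spectrum=spectrum)


def add_poisson_noise(
    image: RadiographImage, photons_per_unit: float, seed: int
) -> RadiographImage:
    """Quantum-noise surrogate for the mAs setting.

    Each pixel value x is replaced by Poisson(x * photons_per_unit) /
    photons_per_unit with a generator seeded by ``seed``; smaller
    ``photons_per_unit`` mimics a lower mAs (noisier image).  Very large
    means (> 1e12) use the Gaussian limit of the Poisson law to stay inside
    integer range; the substitution error is far below the quantisation of
    any output format.
    """
    if not photons_per_unit > 0:
        raise ValueError("photons_per_unit must be positive")
    rng = np.random.default_rng(seed)
    lam = image.pixels * photons_per_unit
    big = lam > 1e12
    noisy = np.empty_like(lam)
    noisy[~big] = rng.poisson(lam[~big]).astype(float)
    if np.any(big):
        noisy[big] = np.round(lam[big] + rng.standard_normal(int(big.sum())) * np.sqrt(lam[big]))
    noisy = np.clip(noisy, 0.0, None) / photons_per_unit
    return replace(image, pixels=noisy, noisy=True)
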