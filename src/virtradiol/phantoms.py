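"""Programmatic test anatomy with closed-form path-length oracles.

Real teaching deployments load commercial patient models; everything in this
package is instead exercised on simple phantoms whose ray chords have exact
analytic formulas: an attenuating slab, nested spheres/cylinders (the inner
mesh displacing the outer material, the same declaration used to nest
trabecular inside cortical bone), and a two-bone "limb" -- a skin cylinder
with two bone capsules meeting at a mid-limb elbow joint plus an ellipsoidal
muscle belly -- that carries a matching two-bone skeleton for posing tests.

All dimensions are mm (limb scale, so full 256x256 radiographs stay cheap);
all meshes are watertight and outward-oriented by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .materials import parse_material_descriptor
from .posing import Bone, Joint, Skeleton
from .projector import SceneTissue, check_mesh

__all__ = ["PhantomSpec", "make_phantom", "analytic_path_length"]

KINDS = ("slab", "nested_spheres", "nested_cylinders", "two_bone_limb")

_DEFAULT_DIMS = {
    "slab": {"width": 100.0, "height": 100.0, "thickness": 10.0},
    "nested_spheres": {"outer_radius": 20.0, "inner_radius": 10.0},
    "nested_cylinders": {"outer_radius": 20.0, "inner_radius": 10.0, "length": 100.0},
    "two_bone_limb": {"length": 300.0, "radius": 40.0, "bone_radius": 10.0},
}

# descriptor, density (None -> descriptor's own density, e.g. from HU)
_DEFAULT_MATERIALS = {
    "slab": {"slab": ("H2O", 1.0)},
    "nested_spheres": {"outer": ("H2O", 1.0), "inner": (1524, None)},
    "nested_cylinders": {"outer": ("H2O", 1.0), "inner": (1524, None)},
    "two_bone_limb": {
        "skin": (0, None),          # water-equivalent soft-tissue envelope
        "bone_upper": (1524, None),  # cortical bone
        "bone_lower": (1524, None),
        "muscle": (45, None),        # soft tissue
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom: kind, dimensions, materials, mesh fineness."""

    kind: str
    dimensions: dict = field(default_factory=dict)
    materials: dict = field(default_factory=dict)
    mesh_resolution: int = 4

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {KINDS}")
        dims = {**_DEFAULT_DIMS[self.kind], **self.dimensions}
        if any(v <= 0 for v in dims.values()):
            raise ValueError(f"phantom dimensions must be positive: {dims}")
        if self.mesh_resolution < 0:
            raise ValueError("mesh_resolution must be >= 0")
        mats = {**_DEFAULT_MATERIALS[self.kind], **self.materials}
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(self, "materials", mats)


def _material(spec: PhantomSpec, part: str):
    desc, density = spec.materials[part]
    return parse_material_descriptor(desc, density=density, name=part)


def _cyl_sections(resolution: int) -> int:
    return 16 * 2 ** max(resolution - 1, 0)


def _axis_x() -> np.ndarray:
    """Rotation taking the +z axis onto +x (cylinders are built along z)."""
    return trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])


def make_phantom(spec: PhantomSpec) -> tuple[list[SceneTissue], Skeleton | None]:
    """Build the phantom's scene tissues (and skeleton, for the limb)."""
    dims = spec.dimensions
    res = spec.mesh_resolution
    scene: list[SceneTissue] = []
    skeleton: Skeleton | None = None

    if spec.kind == "slab":
        mesh = trimesh.creation.box(
            extents=(dims["width"], dims["height"], dims["thickness"])
        )
        scene.append(SceneTissue("slab", mesh, _material(spec, "slab")))

    elif spec.kind == "nested_spheres":
        outer = trimesh.creation.icosphere(subdivisions=res, radius=dims["outer_radius"])
        inner = trimesh.creation.icosphere(subdivisions=res, radius=dims["inner_radius"])
        scene.append(SceneTissue("outer", outer, _material(spec, "outer")))
        scene.append(SceneTissue("inner", inner, _material(spec, "inner"),
                                 parent="outer"))

    elif spec.kind == "nested_cylinders":
        sections = _cyl_sections(res)
        rot = _axis_x()
        outer = trimesh.creation.cylinder(
            radius=dims["outer_radius"], height=dims["length"],
            sections=sections, transform=rot)
        inner = trimesh.creation.cylinder(
            radius=dims["inner_radius"], height=dims["length"],
            sections=sections, transform=rot)
        scene.append(SceneTissue("outer", outer, _material(spec, "outer")))
        scene.append(SceneTissue("inner", inner, _material(spec, "inner"),
                                 parent="outer"))

    elif spec.kind == "two_bone_limb":
        length, radius = dims["length"], dims["radius"]
        bone_r = dims["bone_radius"]
        half = length / 2.0
        sections = _cyl_sections(res)
        skin = trimesh.creation.cylinder(radius=radius, height=length,
                                         sections=sections)
        gap = 2.0 * bone_r   # clearance around the elbow joint
        # each bone spans from bone_r inside the limb end to the elbow gap
        seg = half - gap - 3.0 * bone_r  # cylindrical part of the capsule
        bones = {}
        cap_count = max(sections // 4, 8)
        for name, z0 in (("bone_upper", -half + bone_r),
                         ("bone_lower", gap)):
            cap = trimesh.creation.capsule(height=seg, radius=bone_r,
                                           count=[cap_count, cap_count])
            lo = float(cap.bounds[0][2])
            cap.apply_translation([0.0, 0.0, z0 - lo])
            bones[name] = cap
        muscle = trimesh.creation.icosphere(subdivisions=max(res - 1, 2), radius=1.0)
        muscle.apply_scale([12.0, 12.0, 40.0])
        muscle.apply_translation([24.0, 0.0, -half / 2.0])
        scene.append(SceneTissue("skin", skin, _material(spec, "skin")))
        for name, mesh in bones.items():
            scene.append(SceneTissue(name, mesh, _material(spec, name),
                                     parent="skin"))
        scene.append(SceneTissue("muscle", muscle, _material(spec, "muscle"),
                                 parent="skin"))
        skeleton = Skeleton(
            joints=(
                Joint("proximal", np.array([0.0, 0.0, -half])),
                Joint("elbow", np.array([0.0, 0.0, 0.0]), parent="proximal"),
                Joint("distal", np.array([0.0, 0.0, half]), parent="elbow"),
            ),
            bones=(
                Bone("upper", ("proximal", "elbow"), ("bone_upper",)),
                Bone("lower", ("elbow", "distal"), ("bone_lower",)),
            ),
        )

    for tissue in scene:
        check_mesh(tissue.mesh, tissue.name)
    return scene, skeleton


# ---------------------------------------------------------------------------
# Analytic chord oracles


def _interval_box(origin, direction, lo, hi):
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / direction
        t0 = (lo - origin) * inv
        t1 = (hi - origin) * inv
    tmin = np.nanmax(np.minimum(t0, t1))
    tmax = np.nanmin(np.maximum(t0, t1))
    for a in range(3):
        if direction[a] == 0 and not lo[a] <= origin[a] <= hi[a]:
            return None
    return (tmin, tmax) if tmax > tmin else None


def _interval_sphere(origin, direction, center, radius):
    oc = origin - center
    b = float(np.dot(oc, direction))
    c = float(np.dot(oc, oc)) - radius**2
    disc = b * b - c
    if disc <= 0:
        return None
    s = np.sqrt(disc)
    return (-b - s, -b + s)


def _interval_cylinder_x(origin, direction, radius, half_length):
    # infinite cylinder about the x axis, then clip to |x| <= half_length
    oy, oz = origin[1], origin[2]
    dy, dz = direction[1], direction[2]
    a = dy * dy + dz * dz
    if a < 1e-30:
        radial = (np.hypot(oy, oz) <= radius)
        lateral = (-np.inf, np.inf) if radial else None
    else:
        b = (oy * dy + oz * dz) / a
        c = (oy * oy + oz * oz - radius**2) / a
        disc = b * b - c
        if disc <= 0:
            return None
        s = np.sqrt(disc)
        lateral = (-b - s, -b + s)
    if lateral is None:
        return None
    if direction[0] == 0:
        axial = (-np.inf, np.inf) if abs(origin[0]) <= half_length else None
    else:
        ta = (-half_length - origin[0]) / direction[0]
        tb = (half_length - origin[0]) / direction[0]
        axial = (min(ta, tb), max(ta, tb))
    if axial is None:
        return None
    lo, hi = max(lateral[0], axial[0]), min(lateral[1], axial[1])
    return (lo, hi) if hi > lo else None


def _clip_positive(interval):
    if interval is None:
        return 0.0
    lo, hi = interval
    lo = max(lo, 0.0)
    return max(hi - lo, 0.0)


def analytic_path_length(spec: PhantomSpec, origin, direction) -> dict[str, float]:
    """Exact per-part interior chord lengths (cm) with nesting subtraction.

    Supported kinds: slab, nested_spheres, nested_cylinders (the limb has no
    closed form once posed).  Only the part of each chord ahead of the ray
    origin counts, matching the ray caster.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    dims = spec.dimensions

    if spec.kind == "slab":
        ext = np.array([dims["width"], dims["height"], dims["thickness"]])
        chord = _clip_positive(_interval_box(origin, direction, -ext / 2, ext / 2))
        lengths = {"slab": chord}
    elif spec.kind == "nested_spheres":
        outer = _clip_positive(_interval_sphere(origin, direction,
                                                np.zeros(3), dims["outer_radius"]))
        inner = _clip_positive(_interval_sphere(origin, direction,
                                                np.zeros(3), dims["inner_radius"]))
        lengths = {"outer": max(outer - inner, 0.0), "inner": inner}
    elif spec.kind == "nested_cylinders":
        half = dims["length"] / 2.0
        outer = _clip_positive(_interval_cylinder_x(origin, direction,
                                                    dims["outer_radius"], half))
        inner = _clip_positive(_interval_cylinder_x(origin, direction,
                                                    dims["inner_radius"], half))
        lengths = {"outer": max(outer - inner, 0.0), "inner": inner}
    else:
        raise ValueError(f"no closed-form chord oracle for kind {spec.kind!r}")
    return {part: L / 10.0 for part, L in lengths.items() if L > 0.0}
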