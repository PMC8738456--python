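"""Scene configuration, pipeline orchestration, and run manifests.

A scene config is a YAML/JSON document describing, in procedure order,
everything one simulated exposure needs: the tissue list (mesh paths,
material descriptors, visibility, containment, HU overrides), the
acquisition geometry, the beam (tube settings or a tabulated spectrum
file), an optional skeleton + pose for patient positioning, optional
Poisson noise and display filters, and the output image paths.  A single
config seed governs all randomness, so identical config + inputs always
produce byte-identical raw outputs; each run writes a JSON manifest with
input/output checksums for reproducibility audits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__, display, io
from .geometry import AcquisitionGeometry, CassetteFrame, Collimator
from .materials import load_attenuation_table, parse_material_descriptor
from .posing import (
    Pose,
    Skeleton,
    compute_weights,
    embed_tissues,
    load_pose,
    load_skeleton,
    pose_tissues,
    skin_cage,
    volumetrise,
)
from .projector import (
    SceneTissue,
    add_poisson_noise,
    simulate_radiograph,
    validate_scene,
)
from .spectrum import TubeSettings, load_spectrum, tube_spectrum

__all__ = ["SceneConfig", "load_scene", "run_pipeline", "verify_manifest"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
DEFAULT_LATTICE_SPACING_MM = 10.0


class ConfigError(ValueError):
    """Scene config failed validation; message names the offending field."""


@dataclass
class SceneConfig:
    """Validated scene: everything loaded, checked, ready to run."""

    tissues: list[SceneTissue]
    geometry: AcquisitionGeometry
    spectrum: object                     # Spectrum
    skeleton: Skeleton | None = None
    pose: Pose | None = None
    roles: dict[str, str] = field(default_factory=dict)  # tissue -> skin|bone|organ
    lattice_spacing_mm: float = DEFAULT_LATTICE_SPACING_MM
    noise_photons_per_unit: float | None = None
    filters: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    base_dir: pathlib.Path = pathlib.Path(".")
    source_path: pathlib.Path | None = None


def _require(doc, key, where):
    if key not in doc:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return doc[key]


def _geometry_from(doc, where="geometry"):
    cas_doc = _require(doc, "cassette", where)
    try:
        cassette = CassetteFrame(
            center=np.asarray(_require(cas_doc, "center_xyz_mm", f"{where}.cassette"), float),
            normal=np.asarray(_require(cas_doc, "normal", f"{where}.cassette"), float),
            up=np.asarray(_require(cas_doc, "up", f"{where}.cassette"), float),
            width=float(_require(cas_doc, "width_mm", f"{where}.cassette")),
            height=float(_require(cas_doc, "height_mm", f"{where}.cassette")),
            cols=int(_require(cas_doc, "cols", f"{where}.cassette")),
            rows=int(_require(cas_doc, "rows", f"{where}.cassette")),
        )
        collimator = None
        if doc.get("collimator"):
            col = doc["collimator"]
            collimator = Collimator(
                field_width=float(_require(col, "width_mm", f"{where}.collimator")),
                field_height=float(_require(col, "height_mm", f"{where}.collimator")),
                orientation_deg=float(col.get("orientation_deg", 0.0)),
            )
        return AcquisitionGeometry(
            focus=np.asarray(_require(doc, "focus_xyz_mm", where), float),
            cassette=cassette,
            sid=float(_require(doc, "sid_mm", where)),
            sod=float(_require(doc, "sod_mm", where)),
            collimator=collimator,
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_scene(path) -> SceneConfig:
    """Load and fully validate a scene config (YAML or JSON)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise ConfigError(f"scene config not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if int(doc.get("schema_version", -1)) != SCHEMA_VERSION:
        raise ConfigError(f"{path}: schema_version must be {SCHEMA_VERSION}")
    base = path.parent
    table = load_attenuation_table()

    tissues, roles = [], {}
    for i, tdoc in enumerate(doc.get("tissues", [])):
        where = f"{path}:tissues[{i}]"
        name = _require(tdoc, "name", where)
        mesh_path = base / _require(tdoc, "mesh", where)
        if not mesh_path.exists():
            raise ConfigError(f"{where}: mesh file not found: {mesh_path}")
        mesh = io.read_mesh(mesh_path)
        try:
            material = parse_material_descriptor(
                _require(tdoc, "material", where),
                density=tdoc.get("density"), name=name)
        except ValueError as exc:
            raise ConfigError(f"{where}: {exc}") from exc
        hu = tdoc.get("hu_override")
        tissues.append(SceneTissue(
            name=name, mesh=mesh, material=material,
            visible=bool(tdoc.get("visible", True)),
            parent=tdoc.get("parent"),
            hu_override=None if hu is None else float(hu),
        ))
        roles[name] = tdoc.get("role", "organ")
    if not tissues:
        raise ConfigError(f"{path}: scene declares no tissues")
    try:
        validate_scene(tissues)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    geometry = _geometry_from(_require(doc, "geometry", str(path)))

    sdoc = _require(doc, "spectrum", str(path))
    if "file" in sdoc:
        spec_path = base / sdoc["file"]
        if not spec_path.exists():
            raise ConfigError(f"{path}: spectrum file not found: {spec_path}")
        spectrum = load_spectrum(spec_path)
    else:
        try:
            settings = TubeSettings(
                kvp=float(_require(sdoc, "kvp", f"{path}:spectrum")),
                filtration_mm_al=float(sdoc.get("filtration_mm_al", 2.5)),
                total_photons=float(sdoc.get("total_photons", 1e6)),
            )
        except ValueError as exc:
            raise ConfigError(f"{path}:spectrum: {exc}") from exc
        spectrum = tube_spectrum(settings, table)

    skeleton = pose = None
    if doc.get("skeleton"):
        skel_path = base / doc["skeleton"]
        if not skel_path.exists():
            raise ConfigError(f"{path}: skeleton file not found: {skel_path}")
        skeleton = load_skeleton(skel_path)
    if doc.get("pose"):
        if skeleton is None:
            raise ConfigError(f"{path}: pose given without a skeleton")
        pose_path = base / doc["pose"]
        if not pose_path.exists():
            raise ConfigError(f"{path}: pose file not found: {pose_path}")
        pose = load_pose(pose_path, skeleton)

    noise = doc.get("noise") or {}
    ppu = noise.get("photons_per_unit")
    posing = doc.get("posing") or {}
    return SceneConfig(
        tissues=tissues,
        geometry=geometry,
        spectrum=spectrum,
        skeleton=skeleton,
        pose=pose,
        roles=roles,
        lattice_spacing_mm=float(posing.get("lattice_spacing_mm",
                                            DEFAULT_LATTICE_SPACING_MM)),
        noise_photons_per_unit=None if ppu is None else float(ppu),
        filters=list(doc.get("filters", [])),
        outputs=dict(doc.get("outputs", {})),
        seed=int(doc.get("seed", 0)),
        base_dir=base,
        source_path=path,
    )


def _apply_filters(img: display.DisplayImage, filters: list[dict]) -> display.DisplayImage:
    """Apply config filter specs left-to-right to a display image."""
    for i, f in enumerate(filters):
        kind = f.get("type")
        if kind == "log":
            img = display.log_filter(img, float(f["k"]))
        elif kind == "gamma":
            img = display.gamma_filter(img, float(f["gamma"]))
        elif kind == "brightness_contrast":
            img = display.brightness_contrast(img, float(f.get("brightness", 0.0)),
                                              float(f.get("contrast", 1.0)))
        elif kind == "negative":
            img = display.negative(img)
        elif kind == "marker":
            img = display.stamp_side_marker(img, f["side"],
                                            tuple(int(x) for x in f["at"]),
                                            scale=int(f.get("scale", 1)))
        else:
            raise ConfigError(f"filters[{i}]: unknown filter type {kind!r}")
    return img


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def pose_scene_tissues(config: SceneConfig) -> list[SceneTissue]:
    """Run the positioning stages and return tissues deformed to the pose."""
    if config.skeleton is None or config.pose is None:
        return config.tissues
    skins = [t for t in config.tissues if config.roles.get(t.name) == "skin"]
    if len(skins) != 1:
        raise ConfigError("posing requires exactly one tissue with role 'skin'")
    bone_tissues = {t.name: t.mesh for t in config.tissues
                    if t.name in {n for b in config.skeleton.bones for n in b.tissues}}
    bone_by_bone = {
        b.name: bone_tissues[b.tissues[0]] for b in config.skeleton.bones
    }
    cage = volumetrise(skins[0].mesh, bone_by_bone, config.lattice_spacing_mm)
    weights = compute_weights(cage)
    all_meshes = {t.name: t.mesh for t in config.tissues}
    embedding = embed_tissues(all_meshes, cage)
    deformed = skin_cage(cage, weights, config.skeleton, config.pose)
    posed = pose_tissues(all_meshes, embedding, cage, deformed)
    return [SceneTissue(t.name, posed[t.name], t.material, t.visible,
                        t.parent, t.hu_override) for t in config.tissues]


def run_pipeline(config: SceneConfig, out_dir=None) -> dict:
    """Execute pose -> project -> noise -> filters -> outputs; return manifest.

    Outputs resolve relative to ``out_dir`` (default: the config directory).
    The manifest records inputs, seed, package version, stage timings and
    SHA-256 checksums of every written file.
    """
    out_dir = pathlib.Path(out_dir) if out_dir is not None else config.base_dir
    table = load_attenuation_table()
    written: list[pathlib.Path] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    for p in written:
                        p.unlink(missing_ok=True)
                    log.error("stage %r failed: %s", name, exc)
                return False
        return _T()

    try:
        with stage("pose"):
            tissues = pose_scene_tissues(config)
        with stage("project"):
            image = simulate_radiograph(tissues, config.geometry,
                                        config.spectrum, table)
        if config.noise_photons_per_unit is not None:
            with stage("noise"):
                image = add_poisson_noise(image, config.noise_photons_per_unit,
                                          config.seed)
        with stage("write_raw"):
            if "raw" in config.outputs:
                raw_path = out_dir / config.outputs["raw"]
                io.write_raw_image(image, raw_path)
                written.append(raw_path)
        with stage("filters"):
            disp = _apply_filters(display.normalise(image), config.filters)
        with stage("write_display"):
            for key in ("png", "pgm"):
                if key in config.outputs:
                    p = out_dir / config.outputs[key]
                    io.write_display_image(disp, p)
                    written.append(p)
    except Exception:
        raise

    manifest = {
        "package": {"name": "virtradiol", "version": __version__},
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": None if config.source_path is None else {
            "path": str(config.source_path),
            "sha256": _sha256(config.source_path),
        },
        "timings_s": timings,
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in written},
    }
    manifest_path = out_dir / config.outputs.get("manifest", "run_manifest.json")
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest


_DEMO_GEOMETRY = {
    # AP view, beam along -y, limb axis (z) along the cassette "up" vector
    "small": {
        "focus_xyz_mm": [0.0, 900.0, 0.0],
        "cassette": {"center_xyz_mm": [0.0, -100.0, 0.0],
                     "normal": [0.0, 1.0, 0.0], "up": [0.0, 0.0, 1.0],
                     "width_mm": 200.0, "height_mm": 200.0,
                     "cols": 128, "rows": 128},
        "sid_mm": 1000.0, "sod_mm": 900.0,
    },
    "limb": {
        "focus_xyz_mm": [0.0, 900.0, 0.0],
        "cassette": {"center_xyz_mm": [0.0, -100.0, 0.0],
                     "normal": [0.0, 1.0, 0.0], "up": [0.0, 0.0, 1.0],
                     "width_mm": 350.0, "height_mm": 430.0,
                     "cols": 256, "rows": 256},
        "sid_mm": 1000.0, "sod_mm": 900.0,
        "collimator": {"width_mm": 160.0, "height_mm": 400.0,
                       "orientation_deg": 0.0},
    },
}

FLEXION_90_QUAT = [np.sqrt(0.5), -np.sqrt(0.5), 0.0, 0.0]  # -90 deg about x


def write_phantom_bundle(spec, out_dir, kvp: float = 70.0, seed: int = 0) -> pathlib.Path:
    """Emit a ready-to-run lesson bundle for a phantom.

    Writes STL meshes, a ``scene.yaml`` (plus, for the limb, a skeleton,
    rest and 90-degree elbow-flexion pose files and a ``scene_flexed.yaml``
    with collimation, L-marker and gamma 0.8), and returns the main config
    path.  Every emitted config loads cleanly through :func:`load_scene`.
    """
    from .phantoms import PhantomSpec, make_phantom
    from .posing import save_pose, save_skeleton

    if not isinstance(spec, PhantomSpec):
        spec = PhantomSpec(str(spec))
    out_dir = pathlib.Path(out_dir)
    (out_dir / "meshes").mkdir(parents=True, exist_ok=True)
    tissues, skeleton = make_phantom(spec)

    tissue_docs = []
    bone_tissue_names = set()
    if skeleton is not None:
        bone_tissue_names = {n for b in skeleton.bones for n in b.tissues}
    for t in tissues:
        mesh_rel = f"meshes/{t.name}.stl"
        io.write_mesh(t.mesh, out_dir / mesh_rel)
        desc = t.material.source_descriptor
        try:  # numeric descriptors are Hounsfield units
            desc = float(desc.split("=", 1)[1]) if desc.startswith("HU=") else desc
        except (ValueError, IndexError):
            pass
        role = ("skin" if t.name == "skin"
                else "bone" if t.name in bone_tissue_names else "organ")
        tissue_docs.append({
            "name": t.name, "mesh": mesh_rel, "material": desc,
            "density": t.material.density, "visible": t.visible,
            "parent": t.parent, "role": role,
        })

    geom = _DEMO_GEOMETRY["limb" if spec.kind == "two_bone_limb" else "small"]
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "tissues": tissue_docs,
        "geometry": geom,
        "spectrum": {"kvp": kvp, "filtration_mm_al": 2.5, "total_photons": 1e6},
        "outputs": {"raw": "radiograph.vxr", "png": "radiograph.png",
                    "manifest": "run_manifest.json"},
    }
    config_path = out_dir / "scene.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)

    if skeleton is not None:
        save_skeleton(skeleton, out_dir / "skeleton.json")
        save_pose(Pose.identity(skeleton), out_dir / "pose_rest.json")
        flexed = Pose({**{j.name: (1.0, 0.0, 0.0, 0.0) for j in skeleton.joints},
                       "elbow": tuple(FLEXION_90_QUAT)})
        save_pose(flexed, out_dir / "pose_flexion90.json")
        flexed_doc = dict(doc)
        flexed_doc["skeleton"] = "skeleton.json"
        flexed_doc["pose"] = "pose_flexion90.json"
        flexed_doc["posing"] = {"lattice_spacing_mm": DEFAULT_LATTICE_SPACING_MM}
        flexed_doc["filters"] = [
            {"type": "gamma", "gamma": 0.8},
            {"type": "marker", "side": "L", "at": [12, 12], "scale": 4},
        ]
        flexed_doc["outputs"] = {"raw": "radiograph_flexed.vxr",
                                 "png": "radiograph_flexed.png",
                                 "manifest": "run_manifest_flexed.json"}
        with open(out_dir / "scene_flexed.yaml", "w") as fh:
            yaml.safe_dump(flexed_doc, fh, sort_keys=False)
    return config_path


def verify_manifest(manifest_path) -> bool:
    """Re-checksum a run's outputs against its manifest."""
    manifest_path = pathlib.Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return all(_sha256(base / rel) == digest
               for rel, digest in manifest["outputs"].items())
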