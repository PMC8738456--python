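"""Mesh and image input/output.

Meshes (STL/OBJ/PLY, mm) load through trimesh with vertex welding and
outward orientation enforcement, so downstream code can rely on watertight,
positively-oriented surfaces.  Radiographs write in two forms:

* a raw 32-bit float container (``.vxr``): one JSON header line (dimensions,
  pixel pitch, geometry echo) followed by little-endian row-major float32
  pixels -- lossless and byte-reproducible for a fixed scene and seed;
* display formats (16-bit PNG or PGM) of a normalised copy with the
  radiographic negative convention applied (higher exposure renders
  darker), plus any requested display filters already baked in.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import trimesh

from .display import DisplayImage, negative, normalise
from .projector import RadiographImage, check_mesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "write_raw_image",
    "read_raw_image",
    "write_display_image",
]

_WELD_TOL_MM = 1e-6
RAW_MAGIC = "virtradiol-raw-v1"


def read_mesh(path) -> trimesh.Trimesh:
    """Load a triangle mesh (mm): weld vertices, orient outward, validate."""
    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    loaded = trimesh.load(path, force="mesh", process=False)
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise IOError(f"no triangles in mesh file: {path}")
    mesh = trimesh.Trimesh(vertices=loaded.vertices, faces=loaded.faces,
                           process=False)
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(mesh)  # consistent winding, outward orientation
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write STL/OBJ/PLY by extension."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)


def write_raw_image(image: RadiographImage, path) -> None:
    """Raw float32 radiograph: JSON header line + little-endian pixel block."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = image.pixels.shape
    header = {"magic": RAW_MAGIC, "rows": rows, "cols": cols, "dtype": "<f4"}
    if image.geometry is not None:
        cas = image.geometry.cassette
        header["pixel_pitch_mm"] = list(cas.pixel_pitch)
        header["geometry"] = {
            "focus_xyz_mm": image.geometry.focus.tolist(),
            "cassette_center_mm": cas.center.tolist(),
            "sid_mm": image.geometry.sid,
            "sod_mm": image.geometry.sod,
        }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header, sort_keys=True) + "\n").encode())
        fh.write(np.ascontiguousarray(image.pixels, dtype="<f4").tobytes())


def read_raw_image(path) -> tuple[np.ndarray, dict]:
    """Read back a ``.vxr`` raw radiograph: (float32 pixels, header dict)."""
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("magic") != RAW_MAGIC:
            raise IOError(f"not a raw radiograph file: {path}")
        data = np.frombuffer(fh.read(), dtype="<f4")
    pixels = data.reshape(header["rows"], header["cols"])
    return pixels, header


def write_display_image(img: DisplayImage | RadiographImage, path,
                        apply_negative: bool = True) -> None:
    """Write a 16-bit PNG or PGM of the display image.

    A physics image is normalised first; ``apply_negative`` renders higher
    exposure darker (the radiographic film convention).
    """
    if isinstance(img, RadiographImage):
        img = normalise(img)
    if apply_negative:
        img = negative(img)
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(img.pixels * 65535.0).astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix == ".pgm":
        with open(path, "wb") as fh:
            fh.write(f"P5\n{data.shape[1]} {data.shape[0]}\n65535\n".encode())
            fh.write(data.astype(">u2").tobytes())
    elif suffix == ".png":
        from PIL import Image

        Image.fromarray(data).save(path)
    else:
        raise IOError(f"unsupported display image format: {path.suffix}")
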