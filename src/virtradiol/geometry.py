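"""Radiographic acquisition geometry: point source, cassette, collimator.

All lengths are millimetres (radiographic convention: SID is typically
1000-1800 mm), angles in degrees.  The cassette is an ideal planar receptor
described by its centre, a unit normal pointing back toward the source, an
in-plane "up" vector, physical size and pixel grid.  Pixel (0, 0) is the
top-left corner as seen from the source; rows advance opposite ``up``,
columns along ``up x normal``.  Storage is row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CassetteFrame",
    "Collimator",
    "AcquisitionGeometry",
    "pixel_center",
    "pixel_centers",
    "generate_rays",
    "collimator_mask",
    "magnification",
]


def _unit(v, name):
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"{name} must be unit length (|{name}| = {norm:.12g})")
    return v


@dataclass(frozen=True)
class CassetteFrame:
    """Detector plane pose and pixelisation."""

    center: np.ndarray          # mm
    normal: np.ndarray          # unit, toward the source
    up: np.ndarray              # unit, in-plane, perpendicular to normal
    width: float                # mm, along `up x normal` (columns)
    height: float               # mm, along `up` (rows)
    cols: int
    rows: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal, "normal"))
        object.__setattr__(self, "up", _unit(self.up, "up"))
        if abs(float(np.dot(self.normal, self.up))) > 1e-9:
            raise ValueError("up must be perpendicular to normal")
        if not (self.width > 0 and self.height > 0 and self.cols > 0 and self.rows > 0):
            raise ValueError("width, height, cols, rows must all be positive")

    @property
    def col_axis(self) -> np.ndarray:
        """In-plane unit vector along increasing column index."""
        return np.cross(self.up, self.normal)

    @property
    def pixel_pitch(self) -> tuple[float, float]:
        """(row pitch, column pitch) in mm."""
        return self.height / self.rows, self.width / self.cols


@dataclass(frozen=True)
class Collimator:
    """Rectangular field on the cassette plane, rotated about its normal."""

    field_width: float   # mm
    field_height: float  # mm
    orientation_deg: float = 0.0

    def __post_init__(self):
        if self.field_width < 0 or self.field_height < 0:
            raise ValueError("collimator field dimensions must be >= 0")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Point-source projection setup.

    SID (source-to-image distance) and SOD (source-to-object distance) give
    the geometric magnification SID/SOD.  When both focus and cassette are
    set, |focus - cassette.center| must equal SID.
    """

    focus: np.ndarray
    cassette: CassetteFrame
    sid: float
    sod: float
    collimator: Collimator | None = None

    def __post_init__(self):
        object.__setattr__(self, "focus", np.asarray(self.focus, dtype=float))
        if not self.sid > self.sod > 0:
            raise ValueError(f"need sid > sod > 0, got sid={self.sid}, sod={self.sod}")
        d = float(np.linalg.norm(self.focus - self.cassette.center))
        if abs(d - self.sid) > 1e-6 * self.sid:
            raise ValueError(
                f"|focus - cassette.center| = {d:.9g} mm does not match sid = {self.sid:g} mm"
            )


def pixel_center(cassette: CassetteFrame, row: int, col: int) -> np.ndarray:
    """World position (mm) of the centre of pixel (row, col)."""
    if not (0 <= row < cassette.rows and 0 <= col < cassette.cols):
        raise IndexError(f"pixel ({row}, {col}) outside {cassette.rows}x{cassette.cols} grid")
    hpitch, wpitch = cassette.pixel_pitch
    u = (col + 0.5) * wpitch - cassette.width / 2.0    # along col_axis
    v = cassette.height / 2.0 - (row + 0.5) * hpitch   # along up
    return cassette.center + u * cassette.col_axis + v * cassette.up


def pixel_centers(cassette: CassetteFrame) -> np.ndarray:
    """All pixel centres as a (rows, cols, 3) array, row-major."""
    hpitch, wpitch = cassette.pixel_pitch
    cols = (np.arange(cassette.cols) + 0.5) * wpitch - cassette.width / 2.0
    rows = cassette.height / 2.0 - (np.arange(cassette.rows) + 0.5) * hpitch
    u, v = np.meshgrid(cols, rows)  # (rows, cols)
    return (
        cassette.center[None, None, :]
        + u[..., None] * cassette.col_axis[None, None, :]
        + v[..., None] * cassette.up[None, None, :]
    )


def generate_rays(geometry: AcquisitionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel rays: (origin (3,), unit directions (rows, cols, 3)).

    Directions point from the focus to each pixel centre.  A focus lying on
    the cassette plane has no projective meaning and raises.
    """
    cas = geometry.cassette
    off_plane = float(np.dot(geometry.focus - cas.center, cas.normal))
    if abs(off_plane) < 1e-9:
        raise ValueError("focus lies on the cassette plane")
    targets = pixel_centers(cas)
    d = targets - geometry.focus[None, None, :]
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    return geometry.focus.copy(), d


def collimator_mask(geometry: AcquisitionGeometry) -> np.ndarray:
    """Binary (rows, cols) mask of pixels inside the collimated field.

    The field is a rectangle on the cassette plane centred at the central
    axis (focus projected along the cassette normal), with sides
    field_width x field_height rotated by ``orientation_deg`` about the
    normal.  Without a collimator the mask is all ones.
    """
    cas = geometry.cassette
    if geometry.collimator is None:
        return np.ones((cas.rows, cas.cols), dtype=np.uint8)
    col = geometry.collimator
    if col.field_width == 0 or col.field_height == 0:
        return np.zeros((cas.rows, cas.cols), dtype=np.uint8)
    # central-axis intersection with the cassette plane
    axis_point = geometry.focus - float(
        np.dot(geometry.focus - cas.center, cas.normal)
    ) * cas.normal
    centers = pixel_centers(cas) - axis_point[None, None, :]
    theta = np.deg2rad(col.orientation_deg)
    e_w = np.cos(theta) * cas.col_axis + np.sin(theta) * cas.up
    e_h = -np.sin(theta) * cas.col_axis + np.cos(theta) * cas.up
    u = centers @ e_w
    v = centers @ e_h
    inside = (np.abs(u) <= col.field_width / 2.0) & (np.abs(v) <= col.field_height / 2.0)
    return inside.astype(np.uint8)


def magnification(geometry: AcquisitionGeometry) -> float:
    """Geometric magnification SID/SOD."""
    return geometry.sid / geometry.sod
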