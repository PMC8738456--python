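"""Radiographic display pipeline: normalisation, filters, side markers.

Physics images (energy fluence) are immutable; every filter here operates on
a normalised display copy with values in [0, 1].  All filters are pure and
monotone (negative reverses ordering exactly), so anatomy ordering by
exposure survives any enhancement chain.  The radiographic negative
convention -- higher exposure renders darker, so an over-exposed high-kV
image looks "too dark" -- is applied by :func:`negative` at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .projector import RadiographImage

__all__ = [
    "DisplayImage",
    "normalise",
    "log_filter",
    "gamma_filter",
    "brightness_contrast",
    "negative",
    "stamp_side_marker",
    "MARKER_GLYPHS",
]

# 7x5 glyph bitmaps for the mandatory laterality markers
_L = (
    "X....",
    "X....",
    "X....",
    "X....",
    "X....",
    "X....",
    "XXXXX",
)
_R = (
    "XXXX.",
    "X...X",
    "X...X",
    "XXXX.",
    "X.X..",
    "X..X.",
    "X...X",
)
MARKER_GLYPHS: dict[str, np.ndarray] = {
    side: np.array([[c == "X" for c in row] for row in rows], dtype=bool)
    for side, rows in {"L": _L, "R": _R}.items()
}


@dataclass(frozen=True)
class DisplayImage:
    """Display-referred image: values in [0, 1] plus marker annotations."""

    pixels: np.ndarray
    annotations: tuple = ()

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if np.any(px < -1e-12) or np.any(px > 1 + 1e-12):
            raise ValueError("display pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))


def normalise(image: RadiographImage | np.ndarray) -> DisplayImage:
    """Map the image range [min, max] linearly onto [0, 1].

    A constant image has no contrast to stretch and maps to mid-grey (0.5),
    so downstream brightness/contrast behave sensibly.
    """
    px = image.pixels if isinstance(image, RadiographImage) else np.asarray(image, float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return DisplayImage(np.full_like(px, 0.5, dtype=float))
    return DisplayImage((px - lo) / (hi - lo))


def log_filter(img: DisplayImage, k: float) -> DisplayImage:
    """Logarithmic tone curve  out = log(1 + k*in) / log(1 + k),  k > 0.

    Compresses highlights and lifts shadows; approaches the identity as
    k -> 0.
    """
    if not k > 0:
        raise ValueError("log filter strength k must be positive")
    return replace(img, pixels=np.log1p(k * img.pixels) / np.log1p(k))


def gamma_filter(img: DisplayImage, gamma: float) -> DisplayImage:
    """Power-law tone curve  out = in**gamma,  gamma > 0."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return replace(img, pixels=np.power(img.pixels, gamma))


def brightness_contrast(img: DisplayImage, brightness: float = 0.0,
                        contrast: float = 1.0) -> DisplayImage:
    """out = clamp(contrast*(in - 0.5) + 0.5 + brightness, 0, 1)."""
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    out = np.clip(contrast * (img.pixels - 0.5) + 0.5 + brightness, 0.0, 1.0)
    return replace(img, pixels=out)


def negative(img: DisplayImage) -> DisplayImage:
    """Photographic inversion out = 1 - in (the radiographic display step)."""
    return replace(img, pixels=1.0 - img.pixels)


def stamp_side_marker(img: DisplayImage, side: str, position: tuple[int, int],
                      scale: int = 1) -> DisplayImage:
    """Composite an opaque 'L' or 'R' laterality glyph at value 1.0.

    ``position`` is the (row, col) of the glyph's top-left corner; ``scale``
    magnifies the packaged 7x5 bitmap by integer replication.  The glyph
    must fit inside the image; keeping it clear of the area of interest is
    the caller's responsibility, as in clinical practice.
    """
    if side not in MARKER_GLYPHS:
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    if scale < 1:
        raise ValueError("scale must be >= 1")
    glyph = np.kron(MARKER_GLYPHS[side], np.ones((scale, scale), dtype=bool))
    r0, c0 = position
    rows, cols = img.pixels.shape
    gr, gc = glyph.shape
    if not (0 <= r0 and 0 <= c0 and r0 + gr <= rows and c0 + gc <= cols):
        raise ValueError(
            f"marker at {position} with size {gr}x{gc} exceeds {rows}x{cols} image"
        )
    out = img.pixels.copy()
    out[r0:r0 + gr, c0:c0 + gc][glyph] = 1.0
    note = {"side": side, "position": (int(r0), int(c0)), "scale": int(scale)}
    return DisplayImage(out, annotations=img.annotations + (note,))
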