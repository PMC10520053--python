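"""Frame rasterization for visual-oddity riddles.

A frame is a ``side x side`` (default 100x100) 8-bit grayscale raster with a
light background shade drawn from [235, 255] and a single dark ink shade
drawn from [0, 61] used for all surfaces, edges and points in that frame.

Scenes are described in unit coordinates on [0,1]^2 with the origin at the
top-left corner, x growing rightwards (columns) and y downwards (rows).

Rounding rule
-------------
Pixel ``(r, c)`` covers the half-open square ``[c/side, (c+1)/side) x
[r/side, (r+1)/side)``; a unit coordinate ``u`` maps to index
``min(floor(u * side), side - 1)``. Under this rule a horizontal segment
from x=0.2 to x=0.8 at side 100 covers columns 20..80 inclusive (61 pixels).
Primitive interiors/strokes are rasterized with Bresenham/scanline routines
(``skimage.draw``); anti-aliasing is off by default, so every pixel equals
either the background or the ink shade. With ``antialias=True`` stroke edges
take intermediate values strictly between ink and background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw
from skimage.morphology import dilation

BACKGROUND_RANGE = (235, 255)
INK_RANGE = (0, 61)

__all__ = [
    "Frame", "Segment", "Polyline", "Polygon", "Disk", "CircleOutline",
    "EllipseOutline", "Mirrored", "render_frame", "ink_mask",
    "BACKGROUND_RANGE", "INK_RANGE",
]


@dataclass
class Frame:
    """One riddle panel: raster plus the two shades it was drawn with."""

    pixels: np.ndarray          # (side, side) uint8
    background_shade: int
    ink_shade: int

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


# ---------------------------------------------------------------------------
# scene primitives (unit coordinates, x = column axis, y = row axis)
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    p0: tuple[float, float]
    p1: tuple[float, float]
    width: int = 1              # stroke width in pixels

    def points(self):
        return [self.p0, self.p1]


@dataclass
class Polyline:
    vertices: list = field(default_factory=list)
    width: int = 1
    closed: bool = False

    def points(self):
        return list(self.vertices)


@dataclass
class Polygon:
    """Filled polygon (scanline fill)."""

    vertices: list = field(default_factory=list)

    def points(self):
        return list(self.vertices)


@dataclass
class Disk:
    center: tuple[float, float]
    radius: float               # unit-coordinate radius

    def points(self):
        (x, y), r = self.center, self.radius
        return [(x - r, y - r), (x + r, y + r)]


@dataclass
class CircleOutline:
    center: tuple[float, float]
    radius: float
    width: int = 1

    def points(self):
        (x, y), r = self.center, self.radius
        return [(x - r, y - r), (x + r, y + r)]


@dataclass
class EllipseOutline:
    center: tuple[float, float]
    r_x: float
    r_y: float
    rotation: float = 0.0       # radians, about the center
    width: int = 1

    def points(self):
        (x, y) = self.center
        r = max(self.r_x, self.r_y)
        return [(x - r, y - r), (x + r, y + r)]


@dataclass
class Mirrored:
    """A primitive plus its exact mirror image about the frame midline.

    The mirror is applied to the rasterized mask, so the pair is pixel-wise
    symmetric by construction (Bresenham strokes are not otherwise
    guaranteed to mirror exactly).
    """

    prim: object
    axis: str = "v"             # 'v': vertical midline; 'h': horizontal

    def points(self):
        pts = self.prim.points()
        if self.axis == "v":
            return pts + [(1.0 - x, y) for x, y in pts]
        return pts + [(x, 1.0 - y) for x, y in pts]


def _to_px(u: float, side: int) -> int:
    return min(int(np.floor(u * side)), side - 1)


def _check_bounds(prim, side: int) -> None:
    for (x, y) in prim.points():
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(
                f"{type(prim).__name__} extends outside the unit square: "
                f"point ({x:.3f}, {y:.3f})")


def _rc(pt, side: int) -> tuple[int, int]:
    x, y = pt
    return _to_px(y, side), _to_px(x, side)


def _thicken(mask: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return mask
    return dilation(mask, footprint=np.ones((width, width), dtype=bool))


def _prim_mask(prim, side: int) -> np.ndarray:
    """Boolean ink mask of one primitive."""
    mask = np.zeros((side, side), dtype=bool)
    if isinstance(prim, Mirrored):
        base = _prim_mask(prim.prim, side)
        return base | (base[:, ::-1] if prim.axis == "v" else base[::-1, :])
    if isinstance(prim, Segment):
        r0, c0 = _rc(prim.p0, side)
        r1, c1 = _rc(prim.p1, side)
        rr, cc = skdraw.line(r0, c0, r1, c1)
        mask[rr, cc] = True
        mask = _thicken(mask, prim.width)
    elif isinstance(prim, Polyline):
        verts = prim.vertices + ([prim.vertices[0]] if prim.closed else [])
        for a, b in zip(verts[:-1], verts[1:]):
            r0, c0 = _rc(a, side)
            r1, c1 = _rc(b, side)
            rr, cc = skdraw.line(r0, c0, r1, c1)
            mask[rr, cc] = True
        mask = _thicken(mask, prim.width)
    elif isinstance(prim, Polygon):
        rows = [_rc(v, side)[0] for v in prim.vertices]
        cols = [_rc(v, side)[1] for v in prim.vertices]
        rr, cc = skdraw.polygon(rows, cols, shape=(side, side))
        mask[rr, cc] = True
        rr, cc = skdraw.polygon_perimeter(rows, cols, shape=(side, side))
        mask[rr, cc] = True
    elif isinstance(prim, Disk):
        r, c = _rc(prim.center, side)
        rr, cc = skdraw.disk((r, c), max(prim.radius * side, 1.0), shape=(side, side))
        mask[rr, cc] = True
    elif isinstance(prim, CircleOutline):
        r, c = _rc(prim.center, side)
        rr, cc = skdraw.circle_perimeter(r, c, max(int(round(prim.radius * side)), 1),
                                         shape=(side, side))
        mask[rr, cc] = True
        mask = _thicken(mask, prim.width)
    elif isinstance(prim, EllipseOutline):
        r, c = _rc(prim.center, side)
        rr, cc = skdraw.ellipse_perimeter(
            r, c,
            max(int(round(prim.r_y * side)), 1),
            max(int(round(prim.r_x * side)), 1),
            orientation=prim.rotation, shape=(side, side))
        mask[rr, cc] = True
        mask = _thicken(mask, prim.width)
    else:
        raise TypeError(f"unknown primitive type: {type(prim).__name__}")
    return mask


def render_frame(scene, rng: np.random.Generator | None = None, *, side: int = 100,
                 background_shade: int | None = None, ink_shade: int | None = None,
                 antialias: bool = False) -> Frame:
    """Rasterize a list of primitives into a :class:`Frame`.

    Shades are sampled from the frame invariant ranges using ``rng`` unless
    given explicitly. An empty scene yields a pure-background frame.
    Deterministic given (scene, seed/shades).
    """
    if background_shade is None or ink_shade is None:
        if rng is None:
            raise ValueError("render_frame needs an rng when shades are not fixed")
        if background_shade is None:
            background_shade = int(rng.integers(BACKGROUND_RANGE[0], BACKGROUND_RANGE[1] + 1))
        if ink_shade is None:
            ink_shade = int(rng.integers(INK_RANGE[0], INK_RANGE[1] + 1))
    if not BACKGROUND_RANGE[0] <= background_shade <= BACKGROUND_RANGE[1]:
        raise ValueError(f"background shade {background_shade} outside {BACKGROUND_RANGE}")
    if not INK_RANGE[0] <= ink_shade <= INK_RANGE[1]:
        raise ValueError(f"ink shade {ink_shade} outside {INK_RANGE}")

    for prim in scene:
        _check_bounds(prim, side)

    pixels = np.full((side, side), background_shade, dtype=np.uint8)
    if antialias:
        coverage = np.zeros((side, side), dtype=np.float32)
        for prim in scene:
            coverage = np.maximum(coverage, _aa_coverage(prim, side))
        blend = ink_shade * coverage + background_shade * (1.0 - coverage)
        pixels = np.round(blend).astype(np.uint8)
    else:
        mask = np.zeros((side, side), dtype=bool)
        for prim in scene:
            mask |= _prim_mask(prim, side)
        pixels[mask] = ink_shade
    return Frame(pixels=pixels, background_shade=background_shade, ink_shade=ink_shade)


def _aa_coverage(prim, side: int) -> np.ndarray:
    """Fractional ink coverage with anti-aliased strokes where supported."""
    cov = np.zeros((side, side), dtype=np.float32)
    if isinstance(prim, (Segment, Polyline)):
        if isinstance(prim, Segment):
            pairs = [(prim.p0, prim.p1)]
        else:
            verts = prim.vertices + ([prim.vertices[0]] if prim.closed else [])
            pairs = list(zip(verts[:-1], verts[1:]))
        for a, b in pairs:
            r0, c0 = _rc(a, side)
            r1, c1 = _rc(b, side)
            rr, cc, val = skdraw.line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
            cov[rr[keep], cc[keep]] = np.maximum(cov[rr[keep], cc[keep]], val[keep])
    else:
        cov[_prim_mask(prim, side)] = 1.0
    return cov


def ink_mask(frame: Frame) -> np.ndarray:
    """Boolean mask of ink (non-background) pixels.

    Ink shades are <= 61 and backgrounds >= 235, so thresholding at the
    midpoint is exact for aliased frames and conservative for anti-aliased
    ones.
    """
    return frame.pixels < 148
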