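"""Procedural generators for visual-oddity concepts.

Each registered concept owns a scene sampler and a checker. A riddle sample
is six rendered frames: five frames satisfy the concept (the checker accepts
them) and one — the oddity — violates it (the checker rejects it). All other
spatial attributes (positions, sizes, orientations, shades) vary randomly so
that the concept is the only systematic difference.

The default registry holds twelve concepts spanning the classic core-
geometry categories (symmetry, Euclidean relations, metric properties,
figures, topology, chirality and transformations); the framework is
extensible — ``register`` adds further concepts with the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import ConvexHull

from .frame import (CircleOutline, Disk, EllipseOutline, Frame, Mirrored,
                    Polygon, Polyline, Segment, ink_mask, render_frame)

__all__ = [
    "SceneSpec", "GeneratorSpec", "RiddleSample", "GenerationError",
    "default_registry", "register", "generate_riddle", "place_oddity",
]

MAX_RETRIES = 100


class GenerationError(RuntimeError):
    pass


@dataclass
class SceneSpec:
    """Geometric description of one frame before rasterization."""

    primitives: list
    meta: dict = field(default_factory=dict)


@dataclass
class GeneratorSpec:
    """A concept: sampler of satisfying/violating scenes plus its checker."""

    concept_id: str
    category: str
    scene_fn: Callable[[np.random.Generator, bool], SceneSpec]
    checker: Callable[[Frame, dict], bool]


@dataclass
class RiddleSample:
    """Six frames, exactly one of which violates the concept."""

    frames: list
    oddity_index: int
    concept_id: str
    metas: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometric helpers
# ---------------------------------------------------------------------------

def _u(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def _angle_diff(a: float, b: float) -> float:
    """Smallest angular distance between two undirected angles (mod pi)."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def _shoelace(verts) -> float:
    v = np.asarray(verts, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _cross2(e1, e2) -> float:
    return float(e1[0] * e2[1] - e1[1] * e2[0])


def _fit_line_rms(points) -> float:
    """RMS perpendicular distance of points from their best-fit line (PCA)."""
    p = np.asarray(points, dtype=float)
    p = p - p.mean(axis=0)
    cov = p.T @ p / len(p)
    return float(np.sqrt(max(np.linalg.eigvalsh(cov)[0], 0.0)))


# ---------------------------------------------------------------------------
# concept scenes and checkers
# ---------------------------------------------------------------------------

def _scene_mirror_symmetry(rng, odd, axis: str) -> SceneSpec:
    """Disc/segment arrangements mirror-symmetric about the frame midline.

    Symmetric frames use mask-mirrored pairs (pixel-exact symmetry); the
    oddity places the same number of elements independently.
    """
    def put(x, y):
        # axis 'v': mirror across the vertical midline; 'h': horizontal
        return (x, y) if axis == "v" else (y, x)

    prims = []
    for _ in range(int(rng.integers(2, 5))):
        r = _u(rng, 0.04, 0.09)
        if not odd:
            x = _u(rng, r + 0.02, 0.45)
            y = _u(rng, r + 0.02, 0.98 - r)
            prims.append(Mirrored(Disk(put(x, y), r), axis))
        else:
            for _ in range(2):
                x = _u(rng, r + 0.02, 0.98 - r)
                y = _u(rng, r + 0.02, 0.98 - r)
                prims.append(Disk(put(x, y), r))
    for _ in range(int(rng.integers(1, 3))):
        if not odd:
            x0, x1 = _u(rng, 0.06, 0.46), _u(rng, 0.06, 0.46)
            y0, y1 = _u(rng, 0.08, 0.92), _u(rng, 0.08, 0.92)
            prims.append(Mirrored(Segment(put(x0, y0), put(x1, y1), width=2), axis))
        else:
            for _ in range(2):
                x0, x1 = _u(rng, 0.06, 0.94), _u(rng, 0.06, 0.94)
                y0, y1 = _u(rng, 0.08, 0.92), _u(rng, 0.08, 0.92)
                prims.append(Segment(put(x0, y0), put(x1, y1), width=2))
    return SceneSpec(prims, {"axis": axis})


def _check_mirror_symmetry(frame: Frame, meta: dict) -> bool:
    m = ink_mask(frame)
    mm = m[:, ::-1] if meta["axis"] == "v" else m[::-1, :]
    total = int(m.sum() + mm.sum())
    if total == 0:
        return False
    mismatch = int(np.logical_xor(m, mm).sum()) / total
    return mismatch < 0.10


def _scene_parallel_lines(rng, odd) -> SceneSpec:
    theta = _u(rng, 0.0, np.pi)
    angles = [theta, theta, theta]
    if odd:
        delta = _u(rng, np.deg2rad(25), np.pi / 2) * (1 if rng.random() < 0.5 else -1)
        angles[int(rng.integers(0, 3))] = theta + delta
    prims = []
    for a in angles:
        cx, cy = _u(rng, 0.30, 0.70), _u(rng, 0.30, 0.70)
        half = _u(rng, 0.15, 0.22)
        dx, dy = half * np.cos(a), half * np.sin(a)
        prims.append(Segment((cx - dx, cy - dy), (cx + dx, cy + dy), width=2))
    return SceneSpec(prims, {"angles": [float(a) for a in angles]})


def _check_parallel(frame, meta) -> bool:
    ang = meta["angles"]
    worst = max(_angle_diff(a, b) for i, a in enumerate(ang) for b in ang[i + 1:])
    return worst < np.deg2rad(5)


def _scene_right_angle(rng, odd) -> SceneSpec:
    vx, vy = _u(rng, 0.35, 0.65), _u(rng, 0.35, 0.65)
    phi = _u(rng, 0.0, 2 * np.pi)
    if odd:
        beta = _u(rng, 20.0, 70.0)
        if rng.random() < 0.5:
            beta = 180.0 - beta
    else:
        beta = 90.0
    l1, l2 = _u(rng, 0.20, 0.30), _u(rng, 0.20, 0.30)
    p1 = (vx + l1 * np.cos(phi), vy + l1 * np.sin(phi))
    a2 = phi + np.deg2rad(beta)
    p2 = (vx + l2 * np.cos(a2), vy + l2 * np.sin(a2))
    prims = [Segment((vx, vy), p1, width=2), Segment((vx, vy), p2, width=2)]
    return SceneSpec(prims, {"angle_deg": float(beta)})


def _check_right_angle(frame, meta) -> bool:
    return abs(meta["angle_deg"] - 90.0) < 5.0


def _scene_aligned_points(rng, odd) -> SceneSpec:
    for _ in range(MAX_RETRIES):
        n = int(rng.integers(4, 6))
        phi = _u(rng, 0.0, np.pi)
        cx, cy = _u(rng, 0.46, 0.54), _u(rng, 0.46, 0.54)
        ts = np.sort(rng.uniform(-0.30, 0.30, size=n))
        if np.min(np.diff(ts)) < 0.08:
            continue
        pts = np.stack([cx + ts * np.cos(phi), cy + ts * np.sin(phi)], axis=1)
        if odd:
            j = int(rng.integers(0, n))
            d = _u(rng, 0.12, 0.20) * (1 if rng.random() < 0.5 else -1)
            pts[j] += d * np.array([-np.sin(phi), np.cos(phi)])
        if pts.min() < 0.06 or pts.max() > 0.94:
            continue
        prims = [Disk((float(x), float(y)), 0.022) for x, y in pts]
        return SceneSpec(prims, {"points": pts.tolist()})
    raise GenerationError("aligned_points: could not place points in bounds")


def _check_aligned(frame, meta) -> bool:
    return _fit_line_rms(meta["points"]) < 0.02


def _scene_equidistant_points(rng, odd) -> SceneSpec:
    n = 4
    s = _u(rng, 0.12, 0.17)
    gaps = np.full(n - 1, s)
    if odd:
        gaps[int(rng.integers(0, n - 1))] *= _u(rng, 1.7, 2.2)
    phi = _u(rng, 0.0, np.pi)
    cx, cy = _u(rng, 0.44, 0.56), _u(rng, 0.44, 0.56)
    ts = np.concatenate([[0.0], np.cumsum(gaps)])
    ts -= ts.mean()
    pts = np.stack([cx + ts * np.cos(phi), cy + ts * np.sin(phi)], axis=1)
    pts = np.clip(pts, 0.05, 0.95)  # span bounded by construction; clip is safety
    prims = [Disk((float(x), float(y)), 0.022) for x, y in pts]
    return SceneSpec(prims, {"gaps": gaps.tolist()})


def _check_equidistant(frame, meta) -> bool:
    g = np.asarray(meta["gaps"])
    return float(g.std() / g.mean()) < 0.05


def _scene_straight_line(rng, odd) -> SceneSpec:
    psi = _u(rng, 0.0, np.pi)
    cx, cy = _u(rng, 0.45, 0.55), _u(rng, 0.45, 0.55)
    half = _u(rng, 0.25, 0.35)
    a = np.array([cx - half * np.cos(psi), cy - half * np.sin(psi)])
    b = np.array([cx + half * np.cos(psi), cy + half * np.sin(psi)])
    if odd:
        h = _u(rng, 0.15, 0.26) * (1 if rng.random() < 0.5 else -1)
        perp = np.array([-np.sin(psi), np.cos(psi)])
        ctrl = (a + b) / 2 + h * perp
        if not (0.05 <= ctrl[0] <= 0.95 and 0.05 <= ctrl[1] <= 0.95):
            ctrl = (a + b) / 2 - h * perp
        t = np.linspace(0.0, 1.0, 25)[:, None]
        curve = (1 - t) ** 2 * a + 2 * t * (1 - t) * ctrl + t ** 2 * b
    else:
        t = np.linspace(0.0, 1.0, 25)[:, None]
        curve = (1 - t) * a + t * b
    prims = [Polyline([(float(x), float(y)) for x, y in curve], width=2)]
    return SceneSpec(prims, {"curve": curve.tolist(), "chord": [a.tolist(), b.tolist()]})


def _check_straight(frame, meta) -> bool:
    a, b = (np.asarray(p) for p in meta["chord"])
    d = b - a
    d /= np.linalg.norm(d)
    perp = np.array([-d[1], d[0]])
    dev = np.abs((np.asarray(meta["curve"]) - a) @ perp)
    return float(dev.max()) < 0.02


def _scene_circle(rng, odd) -> SceneSpec:
    cx, cy = _u(rng, 0.38, 0.62), _u(rng, 0.38, 0.62)
    r = _u(rng, 0.16, 0.28)
    if odd:
        asp = _u(rng, 0.45, 0.65)
        rot = _u(rng, 0.0, np.pi)
        prim = EllipseOutline((cx, cy), r, r * asp, rotation=rot, width=2)
        meta = {"r_major": r, "r_minor": r * asp}
    else:
        prim = CircleOutline((cx, cy), r, width=2)
        meta = {"r_major": r, "r_minor": r}
    return SceneSpec([prim], meta)


def _check_circle(frame, meta) -> bool:
    return meta["r_minor"] / meta["r_major"] > 0.9


def _scene_convex_quadrilateral(rng, odd) -> SceneSpec:
    for _ in range(MAX_RETRIES):
        pts = rng.uniform(0.18, 0.82, size=(4, 2))
        hull = ConvexHull(pts)
        if len(hull.vertices) != 4:
            continue
        quad = pts[hull.vertices]
        if odd:
            j = int(rng.integers(0, 4))
            mid = (quad[(j - 1) % 4] + quad[(j + 1) % 4]) / 2
            centroid = quad.mean(axis=0)
            quad[j] = mid + _u(rng, 0.3, 0.7) * (centroid - mid) + \
                _u(rng, 0.05, 0.12) * (centroid - mid) / max(np.linalg.norm(centroid - mid), 1e-9)
        cross = []
        for k in range(4):
            e1 = quad[(k + 1) % 4] - quad[k]
            e2 = quad[(k + 2) % 4] - quad[(k + 1) % 4]
            cross.append(_cross2(e1, e2))
        convex = all(c > 1e-4 for c in cross) or all(c < -1e-4 for c in cross)
        if convex == odd:
            continue
        prims = [Polyline([(float(x), float(y)) for x, y in quad], width=2, closed=True)]
        return SceneSpec(prims, {"vertices": quad.tolist()})
    raise GenerationError("convex_quadrilateral: rejection sampling exhausted")


def _check_convex_quad(frame, meta) -> bool:
    q = np.asarray(meta["vertices"])
    cross = []
    for k in range(4):
        e1 = q[(k + 1) % 4] - q[k]
        e2 = q[(k + 2) % 4] - q[(k + 1) % 4]
        cross.append(_cross2(e1, e2))
    return all(c > 0 for c in cross) or all(c < 0 for c in cross)


def _scene_point_inside(rng, odd) -> SceneSpec:
    cx, cy = _u(rng, 0.38, 0.62), _u(rng, 0.38, 0.62)
    r = _u(rng, 0.18, 0.28)
    for _ in range(MAX_RETRIES):
        ang = _u(rng, 0.0, 2 * np.pi)
        d = _u(rng, 1.35 * r, 1.35 * r + 0.2) if odd else _u(rng, 0.0, 0.55 * r)
        px, py = cx + d * np.cos(ang), cy + d * np.sin(ang)
        if 0.06 <= px <= 0.94 and 0.06 <= py <= 0.94:
            prims = [CircleOutline((cx, cy), r, width=2), Disk((px, py), 0.028)]
            return SceneSpec(prims, {"center": [cx, cy], "radius": r, "point": [px, py]})
    raise GenerationError("point_inside: could not place outside point in bounds")


def _check_point_inside(frame, meta) -> bool:
    c = np.asarray(meta["center"])
    p = np.asarray(meta["point"])
    return float(np.linalg.norm(p - c)) <= meta["radius"]


# an asymmetric "flag" silhouette, centered on its bounding box
_FLAG = np.array([
    (0.00, 0.00), (0.00, 0.32), (0.16, 0.32), (0.16, 0.24), (0.06, 0.24),
    (0.06, 0.18), (0.13, 0.18), (0.13, 0.11), (0.06, 0.11), (0.06, 0.00),
]) - np.array([0.08, 0.16])


def _place_flag(center, scale, mirror=False, rot=0.0):
    v = _FLAG * scale
    if mirror:
        v = v * np.array([-1.0, 1.0])
    if rot:
        c, s = np.cos(rot), np.sin(rot)
        v = v @ np.array([[c, s], [-s, c]])
    return v + np.asarray(center)


def _scene_chirality(rng, odd) -> SceneSpec:
    scale = _u(rng, 0.75, 1.1)
    cx, cy = _u(rng, 0.32, 0.68), _u(rng, 0.32, 0.68)
    verts = _place_flag((cx, cy), scale, mirror=odd)
    prims = [Polygon([(float(x), float(y)) for x, y in verts])]
    return SceneSpec(prims, {"handedness": float(np.sign(_shoelace(verts)))})


def _check_chirality(frame, meta) -> bool:
    return meta["handedness"] == float(np.sign(_shoelace(_FLAG)))


def _scene_rotation(rng, odd) -> SceneSpec:
    scale = _u(rng, 0.5, 0.62)
    c1 = (_u(rng, 0.22, 0.32), _u(rng, 0.40, 0.60))
    c2 = (_u(rng, 0.68, 0.78), _u(rng, 0.40, 0.60))
    gamma = _u(rng, np.deg2rad(40), np.deg2rad(320))
    v1 = _place_flag(c1, scale)
    v2 = _place_flag(c2, scale, mirror=odd, rot=gamma)
    prims = [Polygon([(float(x), float(y)) for x, y in v1]),
             Polygon([(float(x), float(y)) for x, y in v2])]
    h1, h2 = np.sign(_shoelace(v1)), np.sign(_shoelace(v2))
    return SceneSpec(prims, {"handedness_equal": bool(h1 == h2)})


def _check_rotation(frame, meta) -> bool:
    return meta["handedness_equal"]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, GeneratorSpec] = {}


def register(spec: GeneratorSpec) -> None:
    _REGISTRY[spec.concept_id] = spec


def default_registry() -> dict[str, GeneratorSpec]:
    return dict(_REGISTRY)


for _spec in [
    GeneratorSpec("vertical_symmetry", "symmetrical_figures",
                  lambda rng, odd: _scene_mirror_symmetry(rng, odd, "v"),
                  _check_mirror_symmetry),
    GeneratorSpec("horizontal_symmetry", "symmetrical_figures",
                  lambda rng, odd: _scene_mirror_symmetry(rng, odd, "h"),
                  _check_mirror_symmetry),
    GeneratorSpec("parallel_lines", "euclidean_geometry",
                  _scene_parallel_lines, _check_parallel),
    GeneratorSpec("right_angle", "euclidean_geometry",
                  _scene_right_angle, _check_right_angle),
    GeneratorSpec("aligned_points", "euclidean_geometry",
                  _scene_aligned_points, _check_aligned),
    GeneratorSpec("equidistant_points", "metric_properties",
                  _scene_equidistant_points, _check_equidistant),
    GeneratorSpec("straight_line", "euclidean_geometry",
                  _scene_straight_line, _check_straight),
    GeneratorSpec("circle", "geometrical_figures",
                  _scene_circle, _check_circle),
    GeneratorSpec("convex_quadrilateral", "geometrical_figures",
                  _scene_convex_quadrilateral, _check_convex_quad),
    GeneratorSpec("point_inside", "topology",
                  _scene_point_inside, _check_point_inside),
    GeneratorSpec("chirality", "chiral_figures",
                  _scene_chirality, _check_chirality),
    GeneratorSpec("rotation", "geometrical_transformations",
                  _scene_rotation, _check_rotation),
]:
    register(_spec)


# ---------------------------------------------------------------------------
# riddle assembly
# ---------------------------------------------------------------------------

def place_oddity(non_oddities: list, oddity, rng: np.random.Generator):
    """Shuffle five concept-satisfying items and the oddity into a random
    order; return the shuffled list and the oddity's index."""
    order = rng.permutation(6)
    items: list = [None] * 6
    for slot, item_idx in enumerate(order):
        items[slot] = oddity if item_idx == 5 else non_oddities[item_idx]
    oddity_index = int(np.where(order == 5)[0][0])
    return items, oddity_index


def _sample_frame(spec: GeneratorSpec, rng, odd: bool, side: int, antialias: bool):
    for _ in range(MAX_RETRIES):
        scene = spec.scene_fn(rng, odd)
        frame = render_frame(scene.primitives, rng, side=side, antialias=antialias)
        if spec.checker(frame, scene.meta) == (not odd):
            return frame, scene.meta
    raise GenerationError(
        f"concept {spec.concept_id!r}: could not sample a "
        f"{'violating' if odd else 'satisfying'} frame in {MAX_RETRIES} tries")


def generate_riddle(concept_id: str, rng: np.random.Generator,
                    registry: dict[str, GeneratorSpec] | None = None,
                    side: int = 100, antialias: bool = False) -> RiddleSample:
    """Generate one riddle: five concept frames, one oddity, shuffled.

    Frames are re-rendered with fresh shades until all fifteen unordered
    pairs are pixel-wise distinct (bounded retries).
    """
    reg = registry if registry is not None else _REGISTRY
    if concept_id not in reg:
        raise ValueError(f"unknown concept {concept_id!r}; "
                         f"registered: {sorted(reg)}")
    spec = reg[concept_id]
    rendered = []
    for i in range(6):
        odd = i == 5
        frame, meta = _sample_frame(spec, rng, odd, side, antialias)
        rendered.append((frame, meta))

    # enforce pixel-wise uniqueness across all frames
    for i in range(1, 6):
        retries = 0
        while any(np.array_equal(rendered[i][0].pixels, rendered[j][0].pixels)
                  for j in range(i)):
            if retries >= MAX_RETRIES:
                raise GenerationError(
                    f"concept {concept_id!r}: could not make frame {i} pixel-wise unique")
            frame, meta = _sample_frame(spec, rng, i == 5, side, antialias)
            rendered[i] = (frame, meta)
            retries += 1

    pairs, oddity_index = place_oddity(rendered[:5], rendered[5], rng)
    frames = [f for f, _ in pairs]
    metas = [m for _, m in pairs]
    return RiddleSample(frames=frames, oddity_index=oddity_index,
                        concept_id=concept_id, metas=metas)
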