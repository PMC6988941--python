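"""Synthetic indoor scenes with exact ground truth.

Generates shaded box-room interiors (floor, walls and ceiling polygons from
the pinhole projection of a cuboid seen in one-point perspective) populated
with parametric object silhouettes, together with the exact structural-edge
map (the projected wall/floor/ceiling intersection segments), per-instance
visibility masks, and detection-style confidence scores that decrease with
the occluded fraction of each object.  Everything is deterministic given
the seed, so the full stimulus pipeline and the psychophysics experiment
are testable without any external image set.

Objects are flat silhouettes composed of rectangles and ellipses (a toilet
is an ellipse plus a tank box, a table is a top with legs, ...).  That is
sufficient here because every downstream consumer — the schematic OMS
renderer, the edge detector, the luminance sampler — only ever sees masks
and luminance, never texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

from .annotations import ROOM_LABELS, SceneAnnotation, write_annotation
from .stimuli import EdgeMap, ObjectInstance

__all__ = [
    "ROOM_OBJECT_POOLS",
    "Camera",
    "PlacedObject",
    "RoomSpec",
    "LayoutError",
    "SyntheticScene",
    "sample_room_spec",
    "generate_scene",
    "generate_batch",
    "write_batch",
    "occlusion_scores",
    "structural_edge_segments",
]

#: Object classes plausibly found in each room category; every class is in
#: the schematic pipeline's default allowed set.
ROOM_OBJECT_POOLS: dict[str, tuple[str, ...]] = {
    "bathroom": ("toilet", "sink", "bath"),
    "bedroom": ("bed", "chair", "laptop"),
    "dining_room": ("table", "chair", "chair"),
    "kitchen": ("oven", "microwave", "refrigerator", "sink"),
    "living_room": ("couch", "table", "chair"),
    "office": ("chair", "table", "laptop"),
}

#: Slope of the confidence penalty per unit occluded fraction, and the
#: half-width of the uniform score noise.  The model only needs confidence
#: to correlate negatively with occlusion; the numbers are package choices.
OCCLUSION_SCORE_SLOPE = 0.8
SCORE_NOISE = 0.05


class LayoutError(ValueError):
    """An object footprint falls (partly) outside the image frame."""


@dataclass(frozen=True)
class Camera:
    """Pinhole camera inside a cuboid room, looking at the back wall.

    The camera sits on the room's central axis at ``cam_height`` meters,
    facing +z; the back wall is at distance ``room_d``.  ``focal_px`` is
    derived so the back wall spans roughly the central third of the image.
    """

    image_size: int = 256
    room_w: float = 4.0
    room_h: float = 2.8
    room_d: float = 6.0
    cam_height: float = 1.5

    @property
    def focal_px(self) -> float:
        return 0.6 * self.image_size * self.room_d / self.room_w

    def project(self, x: float, y: float, z: float) -> tuple[float, float]:
        """World (x right, y up, z forward) to image (u right, v down)."""
        c = self.image_size / 2.0
        u = c + self.focal_px * x / z
        v = c - self.focal_px * (y - self.cam_height) / z
        return u, v


@dataclass(frozen=True)
class PlacedObject:
    """One object silhouette placed in the image: class, footprint, depth.

    The footprint is in normalized image coordinates: ``x_center`` and
    ``base_y`` locate the silhouette's bottom-center, ``width`` and
    ``height`` its extent.  ``depth_rank`` orders painting (higher =
    nearer = painted later, occluding what is behind it).
    """

    cls: str
    x_center: float
    base_y: float
    width: float
    height: float
    depth_rank: float
    shade: float = 0.2


@dataclass(frozen=True)
class RoomSpec:
    """Everything needed to render one synthetic scene deterministically."""

    room_label: str
    objects: tuple[PlacedObject, ...]
    camera: Camera = Camera()
    lighting: float = 1.0  # surface-shade contrast multiplier
    clutter_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.room_label not in ROOM_LABELS:
            raise ValueError(f"unknown room label {self.room_label!r}")


@dataclass
class SyntheticScene:
    """A rendered scene image plus its exact ground-truth annotation."""

    annotation: SceneAnnotation
    image: np.ndarray
    occluded_fractions: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# structural edges (cuboid wireframe)

def structural_edge_segments(camera: Camera) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """The eight structural segments in continuous image coordinates.

    Four edges of the back wall plus the four wall/floor and wall/ceiling
    intersection lines receding toward the camera (cut off just in front
    of it, where their projections have left the frame).
    """
    w2 = camera.room_w / 2.0
    h = camera.room_h
    d = camera.room_d
    z_near = 0.35  # close enough that receding edges exit the image
    corners3d = {
        "bl": (-w2, 0.0, d),
        "br": (w2, 0.0, d),
        "tl": (-w2, h, d),
        "tr": (w2, h, d),
    }
    p = {k: camera.project(*v) for k, v in corners3d.items()}
    near = {
        "bl": camera.project(-w2, 0.0, z_near),
        "br": camera.project(w2, 0.0, z_near),
        "tl": camera.project(-w2, h, z_near),
        "tr": camera.project(w2, h, z_near),
    }
    return [
        (p["bl"], p["br"]),  # wall-floor, back
        (p["tl"], p["tr"]),  # wall-ceiling, back
        (p["bl"], p["tl"]),  # wall-wall, left
        (p["br"], p["tr"]),  # wall-wall, right
        (p["bl"], near["bl"]),  # receding floor edges
        (p["br"], near["br"]),
        (p["tl"], near["tl"]),  # receding ceiling edges
        (p["tr"], near["tr"]),
    ]


def _clip_segment(p0, p1, size: int):
    """Liang-Barsky clip of a segment to the image square; None if outside."""
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0),
        (dx, size - 1 - x0),
        (-dy, y0),
        (dy, size - 1 - y0),
    ):
        if p == 0:
            if q < 0:
                return None
            continue
        t = q / p
        if p < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return None
    return (x0 + t0 * dx, y0 + t0 * dy), (x0 + t1 * dx, y0 + t1 * dy)


def _draw_segments(canvas: np.ndarray, segments, value: float = 1.0) -> None:
    size = canvas.shape[0]
    for p0, p1 in segments:
        clipped = _clip_segment(p0, p1, size)
        if clipped is None:
            continue
        (u0, v0), (u1, v1) = clipped
        rr, cc = skdraw.line(int(round(v0)), int(round(u0)), int(round(v1)), int(round(u1)))
        ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        canvas[rr[ok], cc[ok]] = value


def _room_background(camera: Camera, lighting: float) -> np.ndarray:
    """Shaded floor/walls/ceiling polygons of the one-point-perspective room."""
    size = camera.image_size
    img = np.zeros((size, size), dtype=float)
    w2, h, d = camera.room_w / 2.0, camera.room_h, camera.room_d
    bl = camera.project(-w2, 0, d)
    br = camera.project(w2, 0, d)
    tl = camera.project(-w2, h, d)
    tr = camera.project(w2, h, d)

    def shade(base: float) -> float:
        return float(np.clip(0.5 + lighting * (base - 0.5), 0.0, 1.0))

    m = size + 50  # a point safely beyond every border
    # region polygons as (v, u) vertex lists
    regions = [
        ([bl[1], br[1], m, m], [bl[0], br[0], m, -50], shade(0.30)),      # floor
        ([tl[1], tr[1], -50, -50], [tl[0], tr[0], m, -50], shade(0.72)),  # ceiling
        ([tl[1], bl[1], m, -50], [tl[0], bl[0], -50, -50], shade(0.42)),  # left wall
        ([tr[1], br[1], m, -50], [tr[0], br[0], m, m], shade(0.62)),      # right wall
        ([tl[1], tr[1], br[1], bl[1]], [tl[0], tr[0], br[0], bl[0]], shade(0.52)),  # back
    ]
    for vs, us, g in regions:
        rr, cc = skdraw.polygon(np.asarray(vs), np.asarray(us), shape=img.shape)
        img[rr, cc] = g
    return img


# ---------------------------------------------------------------------------
# parametric object silhouettes

def _box(mask, r0, c0, r1, c1):
    r0, r1 = sorted((int(r0), int(r1)))
    c0, c1 = sorted((int(c0), int(c1)))
    mask[max(r0, 0) : r1, max(c0, 0) : c1] = True


def _ellipse(mask, rc, cc, rr_, cr_):
    r, c = skdraw.ellipse(rc, cc, max(rr_, 1), max(cr_, 1), shape=mask.shape)
    mask[r, c] = True


def _silhouette(cls: str, h: int, w: int) -> np.ndarray:
    """Binary silhouette of one object class in an h x w box."""
    m = np.zeros((h, w), dtype=bool)
    if cls == "toilet":
        _box(m, 0, w * 0.55, h * 0.55, w)               # tank
        _ellipse(m, h * 0.55, w * 0.40, h * 0.28, w * 0.40)  # bowl
        _box(m, h * 0.7, w * 0.25, h, w * 0.6)          # base
    elif cls == "sink":
        _ellipse(m, h * 0.22, w * 0.5, h * 0.2, w * 0.48)    # basin
        _box(m, h * 0.3, w * 0.38, h, w * 0.62)         # pedestal
    elif cls == "bath":
        _box(m, h * 0.25, 0, h, w)                      # tub body
        _ellipse(m, h * 0.25, w * 0.5, h * 0.18, w * 0.5)    # rim
    elif cls == "bed":
        _box(m, h * 0.45, 0, h, w)                      # mattress + frame
        _box(m, 0, 0, h * 0.55, w * 0.18)               # headboard
    elif cls == "chair":
        _box(m, 0, 0, h * 0.6, w * 0.22)                # backrest
        _box(m, h * 0.5, 0, h * 0.65, w)                # seat
        _box(m, h * 0.65, w * 0.05, h, w * 0.18)        # front leg
        _box(m, h * 0.65, w * 0.78, h, w * 0.92)        # rear leg
    elif cls == "table":
        _box(m, 0, 0, h * 0.18, w)                      # top
        _box(m, h * 0.18, w * 0.04, h, w * 0.14)        # legs
        _box(m, h * 0.18, w * 0.86, h, w * 0.96)
    elif cls == "couch":
        _box(m, 0, w * 0.08, h * 0.6, w * 0.92)         # backrest
        _box(m, h * 0.35, 0, h, w)                      # seat + arms
    elif cls == "oven":
        _box(m, 0, 0, h, w)
        m[int(h * 0.25) : int(h * 0.8), int(w * 0.15) : int(w * 0.85)] = True
    elif cls == "microwave":
        _box(m, 0, 0, h, w)
    elif cls == "refrigerator":
        _box(m, 0, 0, h, w)
    elif cls == "laptop":
        _box(m, 0, w * 0.1, h * 0.6, w * 0.9)           # screen
        _box(m, h * 0.6, 0, h, w)                       # base
    else:
        _box(m, 0, 0, h, w)
    return m


_CLASS_ASPECT = {  # (height/width of the silhouette box, typical width frac)
    "toilet": (1.3, 0.16),
    "sink": (1.1, 0.14),
    "bath": (0.45, 0.34),
    "bed": (0.55, 0.40),
    "chair": (1.5, 0.16),
    "table": (0.75, 0.32),
    "couch": (0.65, 0.38),
    "oven": (1.1, 0.18),
    "microwave": (0.6, 0.14),
    "refrigerator": (2.0, 0.16),
    "laptop": (0.7, 0.12),
}


def _object_mask(obj: PlacedObject, size: int) -> np.ndarray:
    """Full (pre-occlusion) mask of a placed object; errors if off-frame."""
    w_px = max(int(round(obj.width * size)), 2)
    h_px = max(int(round(obj.height * size)), 2)
    c0 = int(round((obj.x_center - obj.width / 2.0) * size))
    r1 = int(round(obj.base_y * size))
    r0 = r1 - h_px
    if r0 < 0 or r1 > size or c0 < 0 or c0 + w_px > size:
        raise LayoutError(
            f"{obj.cls!r} footprint [{r0}:{r1}, {c0}:{c0 + w_px}] outside {size}x{size} frame"
        )
    full = np.zeros((size, size), dtype=bool)
    full[r0:r1, c0 : c0 + w_px] = _silhouette(obj.cls, h_px, w_px)
    return full


# ---------------------------------------------------------------------------
# occlusion bookkeeping and scoring

def occlusion_scores(
    full_masks: list[np.ndarray],
    depth_order: list[int],
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[float], list[float]]:
    """Visible masks, occluded fractions and confidence scores.

    ``depth_order`` lists indices back-to-front.  The confidence of each
    object is ``clip(1 - 0.8 * occluded_fraction + U(-0.05, 0.05), 0, 1)``,
    mimicking a detector whose score drops for partly hidden objects.
    """
    n = len(full_masks)
    visible = [None] * n
    occluded = [0.0] * n
    nearer = np.zeros(full_masks[0].shape, dtype=bool) if n else None
    for idx in reversed(depth_order):  # front to back: accumulate occluders
        full = full_masks[idx]
        vis = full & ~nearer
        area = full.sum()
        visible[idx] = vis
        occluded[idx] = 1.0 - vis.sum() / area if area else 1.0
        nearer |= full
    noise = rng.uniform(-SCORE_NOISE, SCORE_NOISE, size=n)
    scores = [
        float(np.clip(1.0 - OCCLUSION_SCORE_SLOPE * occ + eps, 0.0, 1.0))
        for occ, eps in zip(occluded, noise)
    ]
    return visible, occluded, scores


# ---------------------------------------------------------------------------
# scene generation

def sample_room_spec(
    room_label: str,
    seed: int,
    camera: Camera | None = None,
    clutter_count: int | None = None,
) -> RoomSpec:
    """Draw a random but valid room layout for one scene.

    Two to four objects from the room's class pool are placed on the floor
    band of the image; nearer objects sit lower in the frame and are drawn
    larger.  Placements are sampled inside safe margins so the layout is
    always renderable.
    """
    rng = np.random.default_rng(seed)
    camera = camera or Camera()
    pool = ROOM_OBJECT_POOLS[room_label]
    n_obj = int(rng.integers(2, 5))
    classes = [pool[int(rng.integers(len(pool)))] for _ in range(n_obj)]
    # always include the room's signature object (first of the pool)
    classes[0] = pool[0]

    objects = []
    for k, cls in enumerate(classes):
        aspect, wfrac = _CLASS_ASPECT[cls]
        width = float(wfrac * rng.uniform(0.85, 1.25))
        base_y = float(rng.uniform(0.62, 0.93))
        scale = 0.55 + 0.8 * (base_y - 0.62)  # nearer -> larger
        width *= scale
        height = min(width * aspect, base_y - 0.02)
        x_center = float(rng.uniform(width / 2 + 0.02, 1.0 - width / 2 - 0.02))
        objects.append(
            PlacedObject(
                cls=cls,
                x_center=x_center,
                base_y=base_y,
                width=width,
                height=height,
                depth_rank=base_y,
                shade=float(rng.uniform(0.05, 0.25)),
            )
        )
    if clutter_count is None:
        clutter_count = int(rng.integers(0, 4))
    return RoomSpec(
        room_label=room_label,
        objects=tuple(objects),
        camera=camera,
        lighting=float(rng.uniform(0.8, 1.2)),
        clutter_count=clutter_count,
        seed=seed,
    )


def generate_scene(spec: RoomSpec, scene_id: str | None = None) -> SyntheticScene:
    """Render one synthetic scene with its exact ground truth.

    The image is the shaded box room with objects painted in depth order;
    the edge map contains exactly the projected cuboid intersection
    segments; instances carry visible-region masks and occlusion-dependent
    confidence scores.  Deterministic given the spec (and its seed).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.camera.image_size
    img = _room_background(spec.camera, spec.lighting)
    segments = structural_edge_segments(spec.camera)
    _draw_segments(img, segments, value=0.08)  # visible seams in the render

    edge_map = np.zeros((size, size), dtype=float)
    _draw_segments(edge_map, segments, value=1.0)

    order = sorted(range(len(spec.objects)), key=lambda i: spec.objects[i].depth_rank)
    full_masks = [_object_mask(obj, size) for obj in spec.objects]
    visible, occluded, scores = occlusion_scores(full_masks, order, rng)

    for idx in order:  # back to front
        img[full_masks[idx]] = spec.objects[idx].shade

    for _ in range(spec.clutter_count):  # distractor blobs, not annotated
        rr = int(rng.integers(size // 2, size - 8))
        cc = int(rng.integers(8, size - 8))
        rad = int(rng.integers(2, max(size // 40, 3)))
        r, c = skdraw.disk((rr, cc), rad, shape=img.shape)
        img[r, c] = float(rng.uniform(0.1, 0.9))

    instances = [
        ObjectInstance(
            label=spec.objects[idx].cls,
            score=round(scores[idx], 6),
            mask=visible[idx],
            index=idx,
        )
        for idx in range(len(spec.objects))
        if visible[idx].any()
    ]
    annotation = SceneAnnotation(
        scene_id=scene_id or f"{spec.room_label}_{spec.seed}",
        room_label=spec.room_label,
        instances=instances,
        edge_map=EdgeMap(edges=edge_map),
    )
    return SyntheticScene(
        annotation=annotation,
        image=np.clip(img, 0.0, 1.0),
        occluded_fractions=[occluded[i.index] for i in instances],
    )


def generate_batch(
    n_per_room: int, seed: int, camera: Camera | None = None
) -> list[SyntheticScene]:
    """Generate ``n_per_room`` scenes for each of the six room categories.

    Child seeds are spawned deterministically from the master seed, so a
    batch is reproducible and scenes are mutually independent.
    """
    if n_per_room < 1:
        raise ValueError("n_per_room must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(6 * n_per_room) % (2**31)
    scenes = []
    k = 0
    for room in ROOM_LABELS:
        for i in range(n_per_room):
            spec = sample_room_spec(room, int(child_seeds[k]), camera=camera)
            scenes.append(generate_scene(spec, scene_id=f"{room}_{i:03d}"))
            k += 1
    return scenes


def write_batch(scenes: list[SyntheticScene], out_dir: str | Path) -> list[Path]:
    """Write a batch to the on-disk scene layout (one directory per scene)."""
    out = Path(out_dir)
    paths = []
    for scene in scenes:
        d = write_annotation(
            scene.annotation, out / scene.annotation.scene_id, image=scene.image
        )
        paths.append(d)
    return paths
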