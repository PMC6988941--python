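"""Stimulus-generation methods: Direct, Edge, and the schematic SIE-OMS.

Three ways of turning an indoor scene into the grayscale image that drives
the phosphene simulator:

* ``direct`` — the scene's luminance itself (per-phosphene averaging then
  happens inside the simulator's sampling step);
* ``edge`` — Canny contours of the luminance image, dilated to survive the
  resolution loss of the phosphene grid;
* ``sie_oms`` — a schematic rendering that composites object masks and
  silhouettes (OMS) as foreground over the room's structural informative
  edges (SIE: wall/floor/ceiling intersection lines) as background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import feature, morphology, transform

__all__ = [
    "DEFAULT_ALLOWED_CLASSES",
    "ObjectInstance",
    "EdgeMap",
    "StimulusImage",
    "to_luminance",
    "resize_to_short_side",
    "direct_stimulus",
    "edge_stimulus",
    "filter_instances",
    "stack_instances",
    "render_oms",
    "compose_sie_oms",
]

#: Indoor object classes kept for the schematic representation; small
#: objects (scissors, banana, ...) and non-indoor classes (car, tree, ...)
#: are discarded because they cannot be identified at phosphene resolution.
DEFAULT_ALLOWED_CLASSES = frozenset(
    {
        "chair",
        "table",
        "couch",
        "toilet",
        "bath",
        "sink",
        "bed",
        "oven",
        "microwave",
        "refrigerator",
        "laptop",
    }
)

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

#: Default processing resolution (short side, px); must exceed the
#: phosphene grid resolution by a comfortable margin.
PROCESSING_SHORT_SIDE = 512


@dataclass(frozen=True)
class ObjectInstance:
    """One segmented object: class label, confidence score, binary mask."""

    label: str
    score: float  # confidence in [0, 1]; range is enforced by validate_annotation
    mask: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a nonempty 2-D raster")
        object.__setattr__(self, "mask", m.astype(bool))


@dataclass(frozen=True)
class EdgeMap:
    """Structural-edge probability map (values in [0, 1])."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 2 or e.size == 0:
            raise ValueError("edge map must be a nonempty 2-D raster")
        if e.min() < 0.0 or e.max() > 1.0:
            raise ValueError("edge map values must lie in [0, 1]")
        object.__setattr__(self, "edges", e)


@dataclass(frozen=True)
class StimulusImage:
    """Processed grayscale stimulus in [0, 1], tagged with its method."""

    pixels: np.ndarray
    method: str = "direct"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("stimulus must be a nonempty 2-D raster")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("stimulus values must lie in [0, 1]")
        if self.method not in {"direct", "edge", "sie_oms"}:
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "pixels", p)


def to_luminance(scene: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) or grayscale raster to [0, 1] luminance (BT.601)."""
    img = np.asarray(scene, dtype=float)
    if img.size == 0:
        raise ValueError("scene is empty")
    if np.issubdtype(np.asarray(scene).dtype, np.integer):
        img = img / 255.0
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    elif img.ndim != 2:
        raise ValueError("scene must be 2-D grayscale or 3-D color")
    return np.clip(img, 0.0, 1.0)


def resize_to_short_side(image: np.ndarray, short_side: int = PROCESSING_SHORT_SIDE) -> np.ndarray:
    """Resize so the shorter side equals ``short_side`` (aspect preserved)."""
    h, w = image.shape[:2]
    s = short_side / min(h, w)
    if s == 1.0:
        return image
    out = transform.resize(
        image, (round(h * s), round(w * s)), anti_aliasing=s < 1.0, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def direct_stimulus(scene: np.ndarray) -> StimulusImage:
    """Direct method: the scene luminance passed through unchanged.

    The per-phosphene brightness averaging happens in the simulator's
    sampling step, so this is the identity on luminance.
    """
    return StimulusImage(pixels=to_luminance(scene), method="direct")


def edge_stimulus(scene: np.ndarray, dilation_radius: int = 1) -> StimulusImage:
    """Edge baseline: Canny contours (default parameters), then dilation.

    Dilation with a disk of ``dilation_radius`` thickens the 1-px Canny
    lines so they survive downsampling to the phosphene grid without
    aliasing away.
    """
    lum = to_luminance(scene)
    edges = feature.canny(lum)  # sigma=1 and default hysteresis thresholds
    if dilation_radius > 0:
        edges = morphology.dilation(edges, morphology.disk(dilation_radius))
    return StimulusImage(pixels=edges.astype(float), method="edge")


def filter_instances(
    instances: Iterable[ObjectInstance],
    allowed: frozenset[str] | set[str] = DEFAULT_ALLOWED_CLASSES,
) -> list[ObjectInstance]:
    """Keep only instances whose class label is in the allowed set."""
    return [inst for inst in instances if inst.label in allowed]


def stack_instances(instances: Sequence[ObjectInstance]) -> list[ObjectInstance]:
    """Painter's order: ascending confidence, ties by input order.

    Detection confidence correlates negatively with occlusion, so the
    most confident instances are the nearest and must be painted last
    (on top of the instances they occlude).
    """
    return sorted(instances, key=lambda inst: inst.score)  # sorted() is stable


def _inner_contour(mask: np.ndarray, thickness: int) -> np.ndarray:
    """Band of ``thickness`` px just inside the mask boundary."""
    if thickness <= 0:
        return np.zeros_like(mask, dtype=bool)
    return mask & ~morphology.erosion(mask, morphology.disk(thickness))


def render_oms(
    instances: Sequence[ObjectInstance],
    shape: tuple[int, int],
    mask_level: float = 0.5,
    contour_level: float = 1.0,
    contour_px: int = 2,
    smooth_radius: int = 1,
) -> StimulusImage:
    """Paint object masks gray with white silhouettes, in painter's order.

    Each instance's mask interior is painted at ``mask_level`` and its
    contour (a band ``contour_px`` wide just inside the mask boundary,
    highlighted to keep overlapping masks distinguishable) at
    ``contour_level``; instances painted later overwrite earlier pixels.
    The final image is smoothed by grayscale morphological closing with a
    disk of ``smooth_radius`` to reduce aliasing (0 disables it).

    ``instances`` must already be in stacking order (see
    :func:`stack_instances`).
    """
    out = np.zeros(shape, dtype=float)
    for inst in instances:
        if inst.mask.shape != shape:
            raise ValueError(
                f"instance {inst.label!r} mask shape {inst.mask.shape} != {shape}"
            )
        out[inst.mask] = mask_level
        out[_inner_contour(inst.mask, contour_px)] = contour_level
    if smooth_radius > 0:
        out = morphology.closing(out, morphology.disk(smooth_radius))
    return StimulusImage(pixels=np.clip(out, 0.0, 1.0), method="sie_oms")


def compose_sie_oms(
    oms: StimulusImage,
    sie: EdgeMap,
    edge_level: float = 1.0,
    edge_width_px: int = 2,
    edge_threshold: float = 0.5,
) -> StimulusImage:
    """Composite: structural edges as background, object masks as foreground.

    The structural-edge probability map is binarized at ``edge_threshold``,
    thickened by dilation to roughly ``edge_width_px`` width and drawn at
    ``edge_level``; every nonzero OMS pixel then overwrites the edges, so
    object masks are never occluded by the room structure.
    """
    if oms.pixels.shape != sie.edges.shape:
        raise ValueError("OMS and SIE rasters must share a shape")
    edges = sie.edges >= edge_threshold
    r = max((edge_width_px - 1) // 2 + (edge_width_px - 1) % 2, 0)
    if r > 0:
        edges = morphology.dilation(edges, morphology.disk(r))
    out = np.where(edges, float(edge_level), 0.0)
    fg = oms.pixels > 0
    out[fg] = oms.pixels[fg]
    return StimulusImage(pixels=np.clip(out, 0.0, 1.0), method="sie_oms")
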