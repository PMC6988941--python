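"""Glue: run one annotated scene through a stimulus method.

Scenes are resampled so the short side reaches the processing resolution
(512 px by default — comfortably above the 32 x 32 phosphene grid) before
any method runs; instance masks and edge maps are resampled alongside with
nearest-neighbour interpolation so they stay binary.
"""

from __future__ import annotations

import numpy as np
from skimage import transform

from .annotations import SceneAnnotation
from .stimuli import (
    PROCESSING_SHORT_SIDE,
    EdgeMap,
    ObjectInstance,
    StimulusImage,
    compose_sie_oms,
    direct_stimulus,
    edge_stimulus,
    filter_instances,
    render_oms,
    stack_instances,
    to_luminance,
)

__all__ = ["process_scene", "METHODS"]

METHODS = ("direct", "edge", "sie_oms")


def _resize_shape(shape: tuple[int, int], short_side: int) -> tuple[int, int]:
    s = short_side / min(shape)
    return (round(shape[0] * s), round(shape[1] * s))


def process_scene(
    image: np.ndarray,
    annotation: SceneAnnotation | None,
    method: str,
    short_side: int | None = PROCESSING_SHORT_SIDE,
) -> StimulusImage:
    """Produce the processed grayscale stimulus for one scene.

    ``annotation`` is required for the schematic ``sie_oms`` method (it
    supplies instances and the structural-edge map) and ignored by the two
    baselines.
    """
    lum = to_luminance(image)
    shape = lum.shape
    if short_side is not None and min(shape) != short_side:
        shape = _resize_shape(lum.shape, short_side)
        lum = np.clip(
            transform.resize(lum, shape, anti_aliasing=min(lum.shape) > short_side),
            0.0,
            1.0,
        )

    if method == "direct":
        return direct_stimulus(lum)
    if method == "edge":
        return edge_stimulus(lum)
    if method != "sie_oms":
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    if annotation is None:
        raise ValueError("sie_oms requires a scene annotation")
    instances = stack_instances(filter_instances(annotation.instances))
    if shape != annotation.edge_map.edges.shape:
        instances = [
            ObjectInstance(
                label=i.label,
                score=i.score,
                mask=transform.resize(i.mask, shape, order=0).astype(bool),
                index=i.index,
            )
            for i in instances
        ]
        edges = transform.resize(annotation.edge_map.edges, shape, order=0)
    else:
        edges = annotation.edge_map.edges
    oms = render_oms(instances, shape)
    return compose_sie_oms(oms, EdgeMap(edges=np.clip(edges, 0.0, 1.0)))
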