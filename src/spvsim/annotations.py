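"""Scene annotation I/O: images, instance masks, edge maps, metadata.

Defines the on-disk layout through which real detector outputs (instance
segmentation + structural-edge networks) or the synthetic oracle supply a
scene to the stimulus pipeline::

    scenes/<scene_id>/
        image.png          # the scene (8-bit gray or RGB)
        edges.png          # structural-edge map (8-bit gray, 0-255 <-> [0,1])
        masks.png          # 16-bit label image, pixel value = mask_id, 0 = bg
        masks/<id>.png     # alternative dialect: one binary PNG per instance
                           # (required when ground-truth masks overlap, which
                           # a label image cannot express)
        meta.json          # room label + instance sidecar [{label, score,
                           # mask_id}, ...]

Coordinates are pixel-based, origin top-left, row-major, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import imageio.v3 as iio
import numpy as np

from .stimuli import EdgeMap, ObjectInstance

__all__ = [
    "ROOM_LABELS",
    "SceneAnnotation",
    "SegmentationProvider",
    "AnnotationError",
    "MissingFileError",
    "MalformedSidecarError",
    "MaskConsistencyError",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
]

#: The six room categories of the indoor-scene experiment.
ROOM_LABELS = (
    "bathroom",
    "bedroom",
    "dining_room",
    "kitchen",
    "living_room",
    "office",
)


class AnnotationError(Exception):
    """Base class for annotation I/O failures."""

    code = "annotation_error"


class MissingFileError(AnnotationError):
    code = "missing_file"


class MalformedSidecarError(AnnotationError):
    code = "malformed_sidecar"


class MaskConsistencyError(AnnotationError):
    code = "mask_mismatch"


@dataclass
class SceneAnnotation:
    """A scene with its ground truth: room label, instances, edge map."""

    scene_id: str
    room_label: str
    instances: list[ObjectInstance]
    edge_map: EdgeMap
    image_path: Path | None = None


class SegmentationProvider(Protocol):
    """Contract for anything that can segment a scene image.

    Abstracts over real networks (instance segmentation + structural-edge
    estimation) and the synthetic ground-truth oracle.
    """

    name: str

    def __call__(
        self, image: np.ndarray
    ) -> tuple[list[ObjectInstance], EdgeMap]: ...


def _load_gray(path: Path) -> np.ndarray:
    if not path.exists():
        raise MissingFileError(f"missing file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr


def read_annotation(scene_dir: str | Path) -> SceneAnnotation:
    """Read one scene directory into a :class:`SceneAnnotation`.

    Supports both mask dialects (label image or per-instance binary PNGs);
    raises a distinct error for a missing file, malformed sidecar, or a
    sidecar/mask-image mismatch.
    """
    d = Path(scene_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise MissingFileError(f"missing file: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
        scene_id = meta["scene_id"]
        room_label = meta["room_label"]
        sidecar = meta["instances"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise MalformedSidecarError(f"malformed sidecar {meta_path}: {exc}") from exc

    edges = _load_gray(d / "edges.png").astype(float) / 255.0
    image_path = d / "image.png"
    if not image_path.exists():
        raise MissingFileError(f"missing file: {image_path}")

    label_img = None
    if (d / "masks.png").exists():
        label_img = iio.imread(d / "masks.png")

    instances: list[ObjectInstance] = []
    for k, entry in enumerate(sidecar):
        try:
            label, score, mask_id = entry["label"], entry["score"], entry["mask_id"]
        except (KeyError, TypeError) as exc:
            raise MalformedSidecarError(
                f"instance {k} in {meta_path} lacks label/score/mask_id"
            ) from exc
        per_inst = d / "masks" / f"{mask_id}.png"
        if per_inst.exists():
            mask = _load_gray(per_inst) > 0
        elif label_img is not None:
            mask = label_img == mask_id
            if not mask.any():
                raise MaskConsistencyError(
                    f"mask_id {mask_id} absent from {d / 'masks.png'}"
                )
        else:
            raise MissingFileError(f"no mask image for mask_id {mask_id} in {d}")
        instances.append(
            ObjectInstance(label=label, score=round(float(score), 6), mask=mask, index=k)
        )

    return SceneAnnotation(
        scene_id=scene_id,
        room_label=room_label,
        instances=instances,
        edge_map=EdgeMap(edges=np.clip(edges, 0.0, 1.0)),
        image_path=image_path,
    )


def write_annotation(
    annotation: SceneAnnotation,
    scene_dir: str | Path,
    image: np.ndarray | None = None,
) -> Path:
    """Write a scene directory; inverse of :func:`read_annotation`.

    Masks are stored as a 16-bit label image when they are disjoint and as
    per-instance binary PNGs when they overlap.  ``image`` is the scene
    raster in [0, 1] (gray) or uint8; if omitted, the annotation's
    ``image_path`` file is copied by reference requirement (it must exist).
    """
    d = Path(scene_dir)
    d.mkdir(parents=True, exist_ok=True)

    if image is None:
        if annotation.image_path is None or not Path(annotation.image_path).exists():
            raise MissingFileError("no scene image provided and image_path missing")
        image = iio.imread(annotation.image_path)
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.asarray(img, dtype=float) * 255.0, 0, 255).round().astype(np.uint8)
    iio.imwrite(d / "image.png", img)
    iio.imwrite(
        d / "edges.png",
        np.clip(annotation.edge_map.edges * 255.0, 0, 255).round().astype(np.uint8),
    )

    masks = [inst.mask for inst in annotation.instances]
    overlap = False
    if masks:
        overlap = np.sum(masks, axis=0).max() > 1
    if masks and not overlap:
        label_img = np.zeros(masks[0].shape, dtype=np.uint16)
        for k, m in enumerate(masks, start=1):
            label_img[m] = k
        iio.imwrite(d / "masks.png", label_img)
    elif masks:
        mdir = d / "masks"
        mdir.mkdir(exist_ok=True)
        for k, m in enumerate(masks, start=1):
            iio.imwrite(mdir / f"{k}.png", (m.astype(np.uint8) * 255))

    sidecar = [
        {"label": inst.label, "score": round(float(inst.score), 6), "mask_id": k}
        for k, inst in enumerate(annotation.instances, start=1)
    ]
    meta = {
        "scene_id": annotation.scene_id,
        "room_label": annotation.room_label,
        "instances": sidecar,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def validate_annotation(annotation: SceneAnnotation) -> list[str]:
    """Return a list of invariant violations (empty iff valid).

    Checks the room label against the six experiment categories, score
    ranges, and that every mask shares the edge map's shape.
    """
    violations: list[str] = []
    if annotation.room_label not in ROOM_LABELS:
        violations.append(
            f"room_label {annotation.room_label!r} not one of {ROOM_LABELS}"
        )
    shape = annotation.edge_map.edges.shape
    for inst in annotation.instances:
        tag = f"instance {inst.index} ({inst.label!r})"
        if not 0.0 <= inst.score <= 1.0:
            violations.append(f"{tag}: score {inst.score} outside [0, 1]")
        if inst.mask.shape != shape:
            violations.append(
                f"{tag}: mask shape {inst.mask.shape} != scene shape {shape}"
            )
        if not inst.mask.any():
            violations.append(f"{tag}: empty mask")
    return violations
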