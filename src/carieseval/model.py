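"""Core data model: boxes, annotations, image and dataset metadata.

Coordinate convention: origin at the top-left corner of the radiograph,
x increases rightward, y downward, units are pixels (real-valued).  Boxes
are closed intervals ``[x_min, x_max] x [y_min, y_max]``, so a centroid
lying exactly on a box edge counts as contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

Session = Literal["pre", "post", "expert"]
SESSIONS: tuple[str, ...] = ("pre", "post", "expert")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel coordinates with strictly positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"non-finite box coordinates: {coords}")
        if any(c < 0 for c in coords):
            raise ValueError(f"negative box coordinates: {coords}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box (zero or negative extent): {coords}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Closed-interval containment: edge points are inside."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def union_hull(self, other: "BoundingBox") -> "BoundingBox":
        """Smallest box covering both boxes."""
        return BoundingBox(
            min(self.x_min, other.x_min),
            min(self.y_min, other.y_min),
            max(self.x_max, other.x_max),
            max(self.y_max, other.y_max),
        )


def hull_of(boxes: Iterable[BoundingBox]) -> BoundingBox:
    """Smallest box covering every box in a non-empty iterable."""
    boxes = list(boxes)
    if not boxes:
        raise ValueError("hull of an empty box collection is undefined")
    return BoundingBox(
        min(b.x_min for b in boxes),
        min(b.y_min for b in boxes),
        max(b.x_max for b in boxes),
        max(b.y_max for b in boxes),
    )


@dataclass(frozen=True)
class Annotation:
    """One annotator's bounding box on one image.

    ``annotation_id`` is assigned by the readers (``<image>:<annotator>:<i>``
    with ``i`` the input order within that image/annotator) and is the handle
    used by match overrides.
    """

    image_id: str
    annotator_id: str
    box: BoundingBox
    session: str = "expert"
    annotation_id: str = ""

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(
                f"unknown session {self.session!r}; expected one of {SESSIONS}"
            )


@dataclass(frozen=True)
class ImageMeta:
    image_id: str
    width: int
    height: int
    n_surfaces: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image {self.image_id}: non-positive dimensions")
        if self.n_surfaces < 1:
            raise ValueError(f"image {self.image_id}: n_surfaces must be >= 1")


@dataclass
class DatasetMeta:
    """A dataset of images with the tooth-surface totals that drive the
    true-negative approximation."""

    dataset_id: str
    images: list[ImageMeta] = field(default_factory=list)

    @property
    def n_surfaces_total(self) -> int:
        return sum(im.n_surfaces for im in self.images)

    @property
    def image_ids(self) -> list[str]:
        return [im.image_id for im in self.images]

    def image(self, image_id: str) -> ImageMeta:
        for im in self.images:
            if im.image_id == image_id:
                return im
        raise KeyError(f"unknown image_id {image_id!r} in dataset {self.dataset_id!r}")

    def __contains__(self, image_id: str) -> bool:
        return any(im.image_id == image_id for im in self.images)


def assign_annotation_ids(annotations: list[Annotation]) -> list[Annotation]:
    """Fill empty annotation_id fields deterministically from input order."""
    counters: dict[tuple[str, str], int] = {}
    out: list[Annotation] = []
    for a in annotations:
        if a.annotation_id:
            out.append(a)
            continue
        key = (a.image_id, a.annotator_id)
        i = counters.get(key, 0)
        counters[key] = i + 1
        out.append(
            Annotation(
                image_id=a.image_id,
                annotator_id=a.annotator_id,
                box=a.box,
                session=a.session,
                annotation_id=f"{a.image_id}:{a.annotator_id}:{i}",
            )
        )
    return out
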