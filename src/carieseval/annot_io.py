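"""Readers and writers for annotation interchange formats.

Everything is normalised to the internal model (:class:`~carieseval.model.Annotation`
plus metadata records).  Three sources are supported:

* Label Studio JSON exports (rectangle labels, percent or pixel coordinates),
* COCO-style JSON (``images[]`` + ``annotations[]`` with ``bbox = [x, y, w, h]``),
* the package's canonical CSV (one row per box).

No image pixels are ever read; only geometry and identifiers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .model import (
    Annotation,
    BoundingBox,
    DatasetMeta,
    ImageMeta,
    assign_annotation_ids,
)

CANONICAL_COLUMNS = [
    "image_id",
    "annotator_id",
    "session",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
]

METADATA_COLUMNS = ["image_id", "width", "height", "n_surfaces"]
ROSTER_COLUMNS = ["annotator_id", "group", "stage"]

ROSTER_GROUPS = {"lecture", "dataset", "ai", "expert"}
ROSTER_STAGES = {"preclinical", "junior", "senior", "na"}


class AnnotationFormatError(ValueError):
    """Malformed or unsupported content in an annotation file."""


def _image_id_from_task(task: dict) -> str:
    data = task.get("data") or {}
    for key in ("image", "img", "url"):
        if key in data and isinstance(data[key], str):
            stem = os.path.basename(data[key])
            return os.path.splitext(stem)[0]
    return str(task.get("id", "unknown"))


def _annotator_id(completed_by: Any) -> str:
    if isinstance(completed_by, dict):
        for key in ("email", "id"):
            if key in completed_by:
                return str(completed_by[key])
        return "unknown"
    return str(completed_by)


def read_label_studio(path: str | os.PathLike, session: str = "expert") -> list[Annotation]:
    """Read a Label Studio JSON export of rectangle labels.

    Rectangle values are interpreted as percentages of ``original_width`` /
    ``original_height`` (Label Studio's default) unless the result object
    carries ``"coordinate_system": "pixel"``, in which case they are absolute
    pixels.  Only rotation-0 rectangles are supported.

    Raises
    ------
    AnnotationFormatError
        On malformed JSON (naming the offending task where possible), rotated
        rectangles, or zero-area boxes (all offenders listed).
    """
    with open(path) as fh:
        try:
            tasks = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationFormatError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(tasks, list):
        raise AnnotationFormatError(f"{path}: expected a top-level list of tasks")

    annotations: list[Annotation] = []
    degenerate: list[str] = []
    for task in tasks:
        task_id = task.get("id", "?")
        image_id = _image_id_from_task(task)
        for ann in task.get("annotations", task.get("completions", [])):
            annotator = _annotator_id(ann.get("completed_by", "unknown"))
            for result in ann.get("result", []):
                if result.get("type") not in (None, "rectanglelabels", "rectangle"):
                    continue
                value = result.get("value")
                if value is None:
                    raise AnnotationFormatError(
                        f"task {task_id}: result without a 'value' field"
                    )
                rotation = float(value.get("rotation", 0.0))
                if rotation != 0.0:
                    raise AnnotationFormatError(
                        f"task {task_id}: rotated rectangles (rotation="
                        f"{rotation}) are not supported"
                    )
                try:
                    x, y = float(value["x"]), float(value["y"])
                    w, h = float(value["width"]), float(value["height"])
                except KeyError as exc:
                    raise AnnotationFormatError(
                        f"task {task_id}: rectangle value missing {exc}"
                    ) from exc
                if result.get("coordinate_system", "percent") == "pixel":
                    x_min, y_min, x_max, y_max = x, y, x + w, y + h
                else:
                    try:
                        ow = float(result["original_width"])
                        oh = float(result["original_height"])
                    except KeyError as exc:
                        raise AnnotationFormatError(
                            f"task {task_id}: percent coordinates require "
                            f"original_width/original_height ({exc} missing)"
                        ) from exc
                    x_min = x / 100.0 * ow
                    y_min = y / 100.0 * oh
                    x_max = (x + w) / 100.0 * ow
                    y_max = (y + h) / 100.0 * oh
                if w <= 0 or h <= 0:
                    degenerate.append(f"task {task_id} ({annotator}@{image_id})")
                    continue
                annotations.append(
                    Annotation(
                        image_id=image_id,
                        annotator_id=annotator,
                        box=BoundingBox(x_min, y_min, x_max, y_max),
                        session=session,
                    )
                )
    if degenerate:
        raise AnnotationFormatError(
            "zero-area rectangles in export: " + "; ".join(degenerate)
        )
    return assign_annotation_ids(annotations)


def read_coco(path: str | os.PathLike, session: str = "expert") -> tuple[list[Annotation], list[ImageMeta]]:
    """Read COCO-style JSON: ``bbox = [x, y, w, h]`` becomes
    ``(x, y, x + w, y + h)`` with no pixel adjustment (COCO coordinates are
    continuous).

    Image records may carry an optional ``n_surfaces`` key (defaults to 1);
    annotations may carry an ``annotator_id`` (defaults to ``"unknown"``).
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationFormatError(f"{path}: malformed JSON: {exc}") from exc

    images: dict[Any, ImageMeta] = {}
    for im in doc.get("images", []):
        image_id = str(im.get("file_name", im["id"]))
        image_id = os.path.splitext(os.path.basename(image_id))[0]
        images[im["id"]] = ImageMeta(
            image_id=image_id,
            width=int(im["width"]),
            height=int(im["height"]),
            n_surfaces=int(im.get("n_surfaces", 1)),
        )

    annotations: list[Annotation] = []
    for ann in doc.get("annotations", []):
        ref = ann["image_id"]
        if ref not in images:
            raise AnnotationFormatError(
                f"annotation {ann.get('id', '?')} references unknown image_id {ref!r}"
            )
        x, y, w, h = (float(v) for v in ann["bbox"])
        if w <= 0 or h <= 0:
            raise AnnotationFormatError(
                f"annotation {ann.get('id', '?')}: zero-area bbox {ann['bbox']}"
            )
        annotations.append(
            Annotation(
                image_id=images[ref].image_id,
                annotator_id=str(ann.get("annotator_id", "unknown")),
                box=BoundingBox(x, y, x + w, y + h),
                session=session,
            )
        )
    return assign_annotation_ids(annotations), list(images.values())


# ---------------------------------------------------------------------------
# canonical CSV formats

def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    rows = [
        {
            "image_id": a.image_id,
            "annotator_id": a.annotator_id,
            "session": a.session,
            "x_min": a.box.x_min,
            "y_min": a.box.y_min,
            "x_max": a.box.x_max,
            "y_max": a.box.y_max,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_annotations_csv(annotations: list[Annotation], path: str | os.PathLike) -> None:
    annotations_to_frame(annotations).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_annotations_csv(path: str | os.PathLike) -> list[Annotation]:
    df = pd.read_csv(
        path,
        dtype={"image_id": str, "annotator_id": str, "session": str},
        float_precision="round_trip",
    )
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {missing}")
    annotations = [
        Annotation(
            image_id=row.image_id,
            annotator_id=row.annotator_id,
            box=BoundingBox(row.x_min, row.y_min, row.x_max, row.y_max),
            session=row.session,
        )
        for row in df.itertuples(index=False)
    ]
    return assign_annotation_ids(annotations)


def read_metadata_csv(path: str | os.PathLike, dataset_id: str | None = None) -> DatasetMeta:
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {missing}")
    images = [
        ImageMeta(row.image_id, int(row.width), int(row.height), int(row.n_surfaces))
        for row in df.itertuples(index=False)
    ]
    if dataset_id is None:
        dataset_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return DatasetMeta(dataset_id=dataset_id, images=images)


def write_metadata_csv(meta: DatasetMeta, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "image_id": im.image_id,
                "width": im.width,
                "height": im.height,
                "n_surfaces": im.n_surfaces,
            }
            for im in meta.images
        ],
        columns=METADATA_COLUMNS,
    ).to_csv(path, index=False)


def read_roster_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {missing}")
    bad_groups = sorted(set(df["group"]) - ROSTER_GROUPS)
    if bad_groups:
        raise AnnotationFormatError(f"{path}: unknown groups {bad_groups}")
    bad_stages = sorted(set(df["stage"]) - ROSTER_STAGES)
    if bad_stages:
        raise AnnotationFormatError(f"{path}: unknown stages {bad_stages}")
    return df[ROSTER_COLUMNS]


def write_report(table: pd.DataFrame, path: str | os.PathLike, round_decimals: int | None = None) -> None:
    """Write a tabular result as CSV with stable column order and a header.

    Floats are written at full precision; when ``round_decimals`` is given,
    a ``<col>_rounded`` display column is appended for every float column.
    """
    out = table.copy()
    if round_decimals is not None:
        for col in table.columns:
            if pd.api.types.is_float_dtype(table[col]):
                out[f"{col}_rounded"] = table[col].round(round_decimals)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Non-fatal findings from cross-checking annotations against metadata."""

    duplicates: list[tuple[str, str, int]] = field(default_factory=list)
    out_of_bounds: list[str] = field(default_factory=list)
    unknown_images: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.duplicates or self.out_of_bounds or self.unknown_images)


def validate_annotations(annotations: list[Annotation], meta: DatasetMeta | None = None) -> ValidationReport:
    """Flag duplicate boxes (kept, never dropped — repeat marking is annotator
    behaviour the evaluation must see) and, when metadata is given, boxes
    outside their image frame or on unknown images."""
    report = ValidationReport()
    seen: dict[tuple, int] = {}
    for a in annotations:
        key = (a.image_id, a.annotator_id, a.box.x_min, a.box.y_min, a.box.x_max, a.box.y_max)
        seen[key] = seen.get(key, 0) + 1
    for (image_id, annotator_id, *_), count in seen.items():
        if count > 1:
            report.duplicates.append((image_id, annotator_id, count))
    if meta is not None:
        for a in annotations:
            if a.image_id not in meta:
                report.unknown_images.append(a.annotation_id or a.image_id)
                continue
            im = meta.image(a.image_id)
            if a.box.x_max > im.width or a.box.y_max > im.height:
                report.out_of_bounds.append(a.annotation_id or a.image_id)
    return report
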