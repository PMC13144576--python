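"""Scoring a candidate annotator against the consensus reference standard.

Candidate boxes are matched to majority-set (S) lesions first, then the
leftovers to minority-set (S′) lesions, by centroid containment against the
lesion's combined box.  Matching is one-to-one: among all assignments of
centroid-matching (candidate, lesion) pairs, the one maximizing the number
of pairs and, among those, the total IoU is chosen (Hungarian algorithm),
so two candidates can never claim the same lesion and no pairing is lost to
ordering effects.  Classification:

* candidate matched to an S lesion            -> true positive (TP)
* candidate matched only to an S′ lesion      -> tentative (neither TP nor FP)
* candidate matched to nothing                -> false positive (FP)
* S lesion left unmatched                     -> false negative (FN)

True negatives have no direct meaning for detection; they are approximated
from tooth-surface counts under the assumption of at most one lesion per
surface:

    TN = N_surfaces − (TP + FP + FN + N_tentative)

where N_tentative is the dataset-level size of the minority set |S′| (not
the per-annotator count of tentative matches).  The per-annotator error
count is FP + FN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .consensus import LesionRecord, ReferenceStandard, centroid_match
from .model import BoundingBox

#: marker for ratios whose denominator is zero (never silently 0.0)
UNDEFINED = float("nan")


def is_defined(value: float) -> bool:
    return not math.isnan(value)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 for disjoint boxes, in [0, 1]."""
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    """Per-image classification of one annotator's candidate boxes."""

    image_id: str
    annotator_id: str
    tp_pairs: list[tuple[BoundingBox, LesionRecord, float]] = field(default_factory=list)
    tentative_pairs: list[tuple[BoundingBox, LesionRecord]] = field(default_factory=list)
    fp_boxes: list[BoundingBox] = field(default_factory=list)
    fn_lesions: list[LesionRecord] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_boxes)

    @property
    def fn(self) -> int:
        return len(self.fn_lesions)

    @property
    def n_tentative(self) -> int:
        return len(self.tentative_pairs)

    @property
    def errors(self) -> int:
        return self.fp + self.fn


@dataclass
class ConfusionSummary:
    """Dataset-level confusion counts for one annotator/session."""

    annotator_id: str
    session: str
    tp: int
    fp: int
    fn: int
    tn: int
    n_tentative_dataset: int
    iou_values: list[float] = field(default_factory=list)

    @property
    def errors(self) -> int:
        return self.fp + self.fn


def _assign_pairs(
    candidates: list[tuple[int, BoundingBox]],
    lesions: list[LesionRecord],
) -> tuple[list[tuple[int, LesionRecord, float]], list[tuple[int, BoundingBox]]]:
    """Optimal one-to-one assignment of centroid-matching (candidate, lesion)
    pairs: maximum pair count, then maximum total IoU (Hungarian algorithm
    with a constant bonus per feasible pair so that cardinality dominates).
    Returns assigned triples and the unassigned candidates."""
    if not candidates or not lesions:
        return [], list(candidates)
    n, m = len(candidates), len(lesions)
    feasible = np.zeros((n, m), dtype=bool)
    ious = np.zeros((n, m))
    bonus = float(max(n, m) + 1)  # one extra pair outweighs any IoU total
    for i, (_, box) in enumerate(candidates):
        for j, lesion in enumerate(lesions):
            if centroid_match(box, lesion.combined_box):
                feasible[i, j] = True
                ious[i, j] = iou(box, lesion.combined_box)
    rows, cols = linear_sum_assignment(feasible * bonus + ious, maximize=True)
    assigned: list[tuple[int, LesionRecord, float]] = []
    used: set[int] = set()
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            idx = candidates[i][0]
            assigned.append((idx, lesions[j], float(ious[i, j])))
            used.add(idx)
    remaining = [(idx, box) for idx, box in candidates if idx not in used]
    return assigned, remaining


def match_candidate(
    candidate_boxes: list[BoundingBox],
    ref: ReferenceStandard,
    image_id: str,
    annotator_id: str = "",
) -> MatchResult:
    """Classify one annotator's boxes on one image against the reference.

    Stage 1 assigns candidates one-to-one to majority (S) lesions; stage 2
    assigns the remaining candidates to minority (S′) lesions; stage 3 labels
    leftovers FP and unmatched S lesions FN.  A candidate matching both an S
    and an S′ lesion is therefore always a TP, never tentative.
    """
    if image_id not in ref.dataset:
        raise KeyError(f"image {image_id!r} is not part of dataset {ref.dataset.dataset_id!r}")

    indexed = list(enumerate(candidate_boxes))
    s_lesions = ref.lesions_on(image_id, "S")
    s_prime_lesions = ref.lesions_on(image_id, "S_prime")

    tp_assigned, remaining = _assign_pairs(indexed, s_lesions)
    tentative_assigned, remaining = _assign_pairs(remaining, s_prime_lesions)

    matched_s = {lesion.lesion_id for _, lesion, _ in tp_assigned}
    result = MatchResult(image_id=image_id, annotator_id=annotator_id)
    result.tp_pairs = [
        (candidate_boxes[idx], lesion, score)
        for idx, lesion, score in sorted(tp_assigned)
    ]
    result.tentative_pairs = [
        (candidate_boxes[idx], lesion) for idx, lesion, _ in sorted(tentative_assigned)
    ]
    result.fp_boxes = [box for _, box in remaining]
    result.fn_lesions = [l for l in s_lesions if l.lesion_id not in matched_s]
    return result


def summarize(
    results: list[MatchResult],
    ref: ReferenceStandard,
    session: str = "pre",
) -> ConfusionSummary:
    """Aggregate per-image match results into a dataset-level confusion
    summary for one annotator, applying the surface-count TN approximation.

    Requires exactly one result per image of the dataset; IoU values of all
    TP pairs are pooled across images.
    """
    if not results:
        raise ValueError("summarize requires at least one MatchResult")
    annotators = {r.annotator_id for r in results}
    if len(annotators) > 1:
        raise ValueError(f"results mix annotators: {sorted(annotators)}")
    seen = {r.image_id for r in results}
    missing = [i for i in ref.dataset.image_ids if i not in seen]
    if missing:
        raise ValueError(f"missing MatchResults for images: {missing}")
    extra = sorted(seen - set(ref.dataset.image_ids))
    if extra:
        raise ValueError(f"results for images outside the dataset: {extra}")

    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    n_tentative = ref.n_minority  # dataset-level |S'|, independent of matching
    tn = ref.dataset.n_surfaces_total - (tp + fp + fn + n_tentative)
    if tn < 0:
        raise ValueError(
            f"TN approximation is negative ({tn}); surface metadata is inconsistent "
            f"with the annotation volume"
        )
    return ConfusionSummary(
        annotator_id=annotators.pop(),
        session=session,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        n_tentative_dataset=n_tentative,
        iou_values=[score for r in results for *_, score in r.tp_pairs],
    )


def evaluate_dataset(
    annotations,
    ref: ReferenceStandard,
    annotator_id: str,
    session: str = "pre",
) -> ConfusionSummary:
    """Convenience wrapper: match one annotator's boxes on every image of the
    dataset (images with no boxes score all-FN) and summarize.

    ``annotations`` is any iterable of :class:`~carieseval.model.Annotation`;
    boxes from other annotators are ignored.
    """
    by_image: dict[str, list] = {i: [] for i in ref.dataset.image_ids}
    for a in annotations:
        if a.annotator_id == annotator_id and a.image_id in by_image:
            by_image[a.image_id].append(a.box)
    results = [
        match_candidate(boxes, ref, image_id, annotator_id)
        for image_id, boxes in by_image.items()
    ]
    return summarize(results, ref, session)


def mean_iou(summary: ConfusionSummary) -> float:
    """Mean IoU over all matched (TP) pairs, pooled across images; NaN when
    the annotator matched nothing."""
    if not summary.iou_values:
        return UNDEFINED
    return sum(summary.iou_values) / len(summary.iou_values)
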