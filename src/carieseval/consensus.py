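"""Multi-expert consensus reference standard.

Three (or more) experienced readers annotate the same radiographs; boxes
drawn by different experts are deemed to refer to the same carious lesion
when the centroid of one lies inside the other (or vice versa).  The
transitive closure of that pairwise relation — connected components of the
match graph — groups boxes into lesions.  A lesion marked by at least two
distinct experts enters the majority set S (ground truth); a lesion marked
by exactly one expert enters the minority set S′ ("tentative": matches to
it later count as neither true nor false positives).

Because centroid containment can chain distinct adjacent lesions together
(typically on adjacent proximal surfaces), a declarative override mechanism
lets a reviewer force or forbid specific pairs before components are formed,
keeping every manual correction auditable in version control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import Annotation, BoundingBox, DatasetMeta, hull_of


def centroid(box: BoundingBox) -> tuple[float, float]:
    """Centre point of a box: ((x_min+x_max)/2, (y_min+y_max)/2)."""
    return box.centroid


def centroid_match(a: BoundingBox, b: BoundingBox) -> bool:
    """True iff the centroid of one box lies inside the other (closed
    intervals: a centroid exactly on an edge matches), or vice versa.
    Symmetric by construction."""
    return b.contains_point(*a.centroid) or a.contains_point(*b.centroid)


@dataclass(frozen=True)
class LesionRecord:
    """One consensus lesion: the combined box, its member expert boxes, and
    the majority/minority label."""

    lesion_id: str
    image_id: str
    combined_box: BoundingBox
    member_annotations: tuple[Annotation, ...]
    n_supporting_experts: int
    set_label: str  # "S" (majority, >= 2 experts) or "S_prime" (exactly 1)

    def __post_init__(self) -> None:
        if self.set_label not in ("S", "S_prime"):
            raise ValueError(f"set_label must be 'S' or 'S_prime', got {self.set_label!r}")


@dataclass(frozen=True)
class MatchOverride:
    """Declarative correction of the automatic matching on one image.

    Pairs are referenced by annotation_id.  A forced pair is always an edge
    of the match graph; a forbidden pair never is.
    """

    image_id: str
    forced_pairs: tuple[tuple[str, str], ...] = ()
    forbidden_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        forced = {frozenset(p) for p in self.forced_pairs}
        forbidden = {frozenset(p) for p in self.forbidden_pairs}
        clash = forced & forbidden
        if clash:
            raise ValueError(f"image {self.image_id}: pairs both forced and forbidden: {sorted(map(sorted, clash))}")


@dataclass
class ReferenceStandard:
    dataset: DatasetMeta
    lesions: list[LesionRecord] = field(default_factory=list)

    @property
    def n_majority(self) -> int:
        return sum(1 for l in self.lesions if l.set_label == "S")

    @property
    def n_minority(self) -> int:
        return sum(1 for l in self.lesions if l.set_label == "S_prime")

    @property
    def n_healthy_surfaces(self) -> int:
        return self.dataset.n_surfaces_total - len(self.lesions)

    def lesions_on(self, image_id: str, set_label: str | None = None) -> list[LesionRecord]:
        out = [l for l in self.lesions if l.image_id == image_id]
        if set_label is not None:
            out = [l for l in out if l.set_label == set_label]
        return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_reference(
    expert_annotations: list[Annotation],
    dataset: DatasetMeta,
    overrides: list[MatchOverride] | None = None,
) -> ReferenceStandard:
    """Build the majority/minority reference standard from expert boxes.

    Per image, an undirected graph over the expert boxes has an edge wherever
    :func:`centroid_match` holds; forbidden override pairs are removed and
    forced pairs added; each connected component becomes one
    :class:`LesionRecord`.  The vote is over distinct experts, not boxes: an
    expert contributing two boxes to one component counts once.  The combined
    box is the smallest box covering all members.

    Raises on an empty expert set or fewer than two distinct experts; warns
    (does not fail) if an image's lesion count exceeds its surface count.
    """
    if not expert_annotations:
        raise ValueError("cannot build a reference standard from zero expert annotations")
    experts = {a.annotator_id for a in expert_annotations}
    if len(experts) < 2:
        raise ValueError(
            f"consensus requires >= 2 distinct experts; got {sorted(experts)}"
        )
    unknown = sorted({a.image_id for a in expert_annotations if a.image_id not in dataset})
    if unknown:
        raise KeyError(f"annotations reference images absent from metadata: {unknown}")

    override_by_image: dict[str, MatchOverride] = {}
    for ov in overrides or []:
        if ov.image_id in override_by_image:
            raise ValueError(f"multiple overrides for image {ov.image_id!r}")
        override_by_image[ov.image_id] = ov

    lesions: list[LesionRecord] = []
    for image in dataset.images:
        members = [a for a in expert_annotations if a.image_id == image.image_id]
        if not members:
            continue
        ov = override_by_image.get(image.image_id)
        forced = {frozenset(p) for p in ov.forced_pairs} if ov else set()
        forbidden = {frozenset(p) for p in ov.forbidden_pairs} if ov else set()

        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = frozenset((members[i].annotation_id, members[j].annotation_id))
                if pair in forbidden:
                    continue
                if pair in forced or centroid_match(members[i].box, members[j].box):
                    uf.union(i, j)

        components: dict[int, list[Annotation]] = {}
        for idx, ann in enumerate(members):
            components.setdefault(uf.find(idx), []).append(ann)

        # deterministic lesion order: by smallest member index within the image
        for k, root in enumerate(sorted(components)):
            comp = components[root]
            n_experts = len({a.annotator_id for a in comp})
            lesions.append(
                LesionRecord(
                    lesion_id=f"{image.image_id}:L{k:03d}",
                    image_id=image.image_id,
                    combined_box=hull_of(a.box for a in comp),
                    member_annotations=tuple(comp),
                    n_supporting_experts=n_experts,
                    set_label="S" if n_experts >= 2 else "S_prime",
                )
            )
        if len(components) > image.n_surfaces:
            warnings.warn(
                f"image {image.image_id}: {len(components)} consensus lesions exceed "
                f"{image.n_surfaces} surfaces; the TN approximation assumes one lesion "
                f"per surface",
                stacklevel=2,
            )

    ref = ReferenceStandard(dataset=dataset, lesions=lesions)
    if ref.n_healthy_surfaces < 0:
        raise ValueError(
            f"dataset {dataset.dataset_id}: lesion count {len(lesions)} exceeds total "
            f"surfaces {dataset.n_surfaces_total}; surface metadata is inconsistent"
        )
    return ref


def prevalence_range(ref: ReferenceStandard) -> tuple[float, float]:
    """Per-surface caries prevalence bracket, in percent.

    The lower bound counts only majority lesions (|S| / total surfaces),
    the upper bound includes the tentative minority set ((|S|+|S′|) / total).
    """
    total = ref.dataset.n_surfaces_total
    if total == 0:
        raise ValueError("prevalence is undefined for a dataset with zero surfaces")
    low = 100.0 * ref.n_majority / total
    high = 100.0 * (ref.n_majority + ref.n_minority) / total
    return low, high


# ---------------------------------------------------------------------------
# persistence

REFERENCE_COLUMNS = [
    "lesion_id",
    "image_id",
    "set_label",
    "n_supporting_experts",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
]


def reference_to_frame(ref: ReferenceStandard) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lesion_id": l.lesion_id,
                "image_id": l.image_id,
                "set_label": l.set_label,
                "n_supporting_experts": l.n_supporting_experts,
                "x_min": l.combined_box.x_min,
                "y_min": l.combined_box.y_min,
                "x_max": l.combined_box.x_max,
                "y_max": l.combined_box.y_max,
            }
            for l in ref.lesions
        ],
        columns=REFERENCE_COLUMNS,
    )


def write_reference_csv(ref: ReferenceStandard, path) -> None:
    reference_to_frame(ref).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_reference_csv(path, dataset: DatasetMeta) -> ReferenceStandard:
    """Load lesion records written by :func:`write_reference_csv`.

    Member expert annotations are not persisted in the CSV; reloaded records
    carry empty member tuples, which is sufficient for evaluation (matching
    uses only the combined box and set label).
    """
    df = pd.read_csv(
        path,
        dtype={"lesion_id": str, "image_id": str, "set_label": str},
        float_precision="round_trip",
    )
    lesions = [
        LesionRecord(
            lesion_id=row.lesion_id,
            image_id=row.image_id,
            combined_box=BoundingBox(row.x_min, row.y_min, row.x_max, row.y_max),
            member_annotations=(),
            n_supporting_experts=int(row.n_supporting_experts),
            set_label=row.set_label,
        )
        for row in df.itertuples(index=False)
    ]
    return ReferenceStandard(dataset=dataset, lesions=lesions)


def read_overrides(path) -> list[MatchOverride]:
    """Read overrides from JSON or YAML: a list of
    ``{image_id, force: [[id, id], ...], forbid: [[id, id], ...]}``."""
    text = open(path).read()
    try:
        entries = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        entries = yaml.safe_load(text)
    if entries is None:
        return []
    return [
        MatchOverride(
            image_id=str(e["image_id"]),
            forced_pairs=tuple(tuple(p) for p in e.get("force", [])),
            forbidden_pairs=tuple(tuple(p) for p in e.get("forbid", [])),
        )
        for e in entries
    ]
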