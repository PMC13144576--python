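"""Synthetic bitewing reader studies.

The generator emulates the structure of a two-dataset pre/post training
study: ~50 radiographs per dataset, ~20 tooth surfaces per image laid out as
disjoint grid cells, per-surface true-lesion prevalence around 20%, a panel
of three experts whose imperfect, difficulty-dependent detection produces a
majority set S and minority set S′ with |S′|/|S| near the 51/132 observed in
real bitewing panels, and student annotators whose sensitivity /
false-alarm profiles shift between a pre and a post session according to
the training method.

Key modelling choices (see docs/methods.md for rationale):

* each surface holds at most one lesion, so the surface-count TN
  approximation is exact in simulation and testable as an identity;
* every true lesion carries a latent difficulty d ~ Beta(a, b); an
  annotator's per-lesion detection probability interpolates linearly from
  ``hit_prob_majority`` (d = 0, obvious lesion) to ``hit_prob_minority``
  (d = 1, barely visible).  Difficulty is what produces single-expert
  (minority) lesions — the abstraction of incipient caries;
* student profiles default to a flat detection probability
  (``hit_prob_minority == hit_prob_majority``), which makes the profile's
  hit probability equal to the expected measured sensitivity against S;
* box jitter (corner noise + log-normal scale noise) is resampled until the
  centroid-containment relation with the true box survives, so default
  noise never breaks matching; a switch allows containment-breaking jitter
  for matcher stress tests;
* one global seed expands into per-annotator substreams keyed by annotator
  id, so adding an annotator never perturbs anyone else's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annot_io import write_annotations_csv, write_metadata_csv
from .consensus import ReferenceStandard, centroid_match
from .model import Annotation, BoundingBox, DatasetMeta, ImageMeta, assign_annotation_ids


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioural parameters of one simulated annotator.

    ``hit_prob_majority`` / ``hit_prob_minority`` are the detection
    probabilities at difficulty 0 and 1; ``fp_rate_per_surface`` is the
    probability of a false alarm on each lesion-free surface; ``jitter_sd``
    (pixels) and ``box_scale_sd`` (log-scale ratio) control box noise.
    """

    annotator_id: str
    hit_prob_majority: float
    hit_prob_minority: float
    fp_rate_per_surface: float
    jitter_sd: float = 0.0
    box_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("hit_prob_majority", "hit_prob_minority", "fp_rate_per_surface"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.jitter_sd < 0 or self.box_scale_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def detection_prob(self, difficulty: float) -> float:
        return self.hit_prob_majority * (1.0 - difficulty) + self.hit_prob_minority * difficulty


def student_profile(annotator_id: str, hit_prob: float, fp_rate: float,
                    jitter_sd: float = 6.0, box_scale_sd: float = 0.25) -> AnnotatorProfile:
    """Flat-difficulty student profile: measured sensitivity converges to
    ``hit_prob``."""
    return AnnotatorProfile(annotator_id, hit_prob, hit_prob, fp_rate, jitter_sd, box_scale_sd)


#: Expert panel default: near-certain detection of obvious lesions, rare
#: detection of the hardest ones; no false alarms (expert disagreement is
#: carried entirely by the difficulty mechanism).
DEFAULT_EXPERT_PROFILE = AnnotatorProfile(
    annotator_id="expert",
    hit_prob_majority=0.95,
    hit_prob_minority=0.05,
    fp_rate_per_surface=0.0,
    jitter_sd=2.0,
    box_scale_sd=0.08,
)

#: Group mean profiles (pre, post), derived from the published group-level
#: sensitivity and specificity means: the lecture raises specificity, the
#: annotated dataset raises sensitivity, the AI tool improves both.
DEFAULT_GROUP_PROFILES: dict[str, tuple[AnnotatorProfile, AnnotatorProfile]] = {
    "lecture": (student_profile("lecture", 0.75, 0.034), student_profile("lecture", 0.73, 0.014)),
    "dataset": (student_profile("dataset", 0.62, 0.018), student_profile("dataset", 0.78, 0.012)),
    "ai": (student_profile("ai", 0.68, 0.026), student_profile("ai", 0.73, 0.004)),
}

DEFAULT_STUDENTS_PER_GROUP = {"lecture": 16, "dataset": 17, "ai": 19}
STAGES = ("preclinical", "junior", "senior")


@dataclass
class StudyConfig:
    n_images: int = 50
    surfaces_per_image: int = 20
    image_width: int = 1000
    image_height: int = 500
    prevalence: float = 0.21
    n_experts: int = 3
    expert_profile: AnnotatorProfile = DEFAULT_EXPERT_PROFILE
    group_profiles: dict[str, tuple[AnnotatorProfile, AnnotatorProfile]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES)
    )
    n_students_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STUDENTS_PER_GROUP)
    )
    difficulty_alpha: float = 1.0
    difficulty_beta: float = 1.5
    ability_sd: float = 0.10
    fp_log_sd: float = 0.5
    preserve_containment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 0.5:
            raise ValueError(f"prevalence must be in [0, 0.5], got {self.prevalence}")
        if self.n_experts < 2:
            raise ValueError("consensus needs at least 2 experts")
        if self.n_images < 1 or self.surfaces_per_image < 1:
            raise ValueError("n_images and surfaces_per_image must be >= 1")
        unknown = set(self.n_students_per_group) - set(self.group_profiles)
        if unknown:
            raise ValueError(f"student counts for groups without profiles: {sorted(unknown)}")


@dataclass(frozen=True)
class TrueLesion:
    lesion_id: str
    image_id: str
    surface_index: int
    box: BoundingBox
    difficulty: float


@dataclass
class GroundTruth:
    meta: DatasetMeta
    lesions: list[TrueLesion]

    def lesions_on(self, image_id: str) -> list[TrueLesion]:
        return [l for l in self.lesions if l.image_id == image_id]


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _id_key(annotator_id: str) -> int:
    return zlib.crc32(annotator_id.encode())


def _surface_cell(config: StudyConfig, surface_index: int) -> tuple[float, float, float, float]:
    """Disjoint grid cell (x0, y0, w, h) of one surface on the image."""
    rows = 2 if config.surfaces_per_image % 2 == 0 else 1
    cols = config.surfaces_per_image // rows
    cw = config.image_width / cols
    ch = config.image_height / rows
    r, c = divmod(surface_index, cols)
    return c * cw, r * ch, cw, ch


def _draw_box_in_cell(rng: np.random.Generator, cell: tuple[float, float, float, float]) -> BoundingBox:
    x0, y0, cw, ch = cell
    w = rng.uniform(0.25, 0.5) * cw
    h = rng.uniform(0.25, 0.5) * ch
    bx = x0 + rng.uniform(0.02 * cw, cw - w - 0.02 * cw)
    by = y0 + rng.uniform(0.02 * ch, ch - h - 0.02 * ch)
    return BoundingBox(bx, by, bx + w, by + h)


def generate_ground_truth(config: StudyConfig, dataset_id: str = "D0", dataset_index: int = 0) -> GroundTruth:
    """Lay surfaces out on a grid and seed each with a lesion at the
    configured prevalence; each lesion gets a latent difficulty
    ~ Beta(difficulty_alpha, difficulty_beta)."""
    rng = _stream(config.seed, 0, dataset_index)
    images = [
        ImageMeta(f"{dataset_id}_img{i:03d}", config.image_width, config.image_height, config.surfaces_per_image)
        for i in range(config.n_images)
    ]
    meta = DatasetMeta(dataset_id=dataset_id, images=images)
    lesions: list[TrueLesion] = []
    for im in images:
        for s in range(config.surfaces_per_image):
            if rng.random() >= config.prevalence:
                continue
            box = _draw_box_in_cell(rng, _surface_cell(config, s))
            lesions.append(
                TrueLesion(
                    lesion_id=f"{im.image_id}:T{s:02d}",
                    image_id=im.image_id,
                    surface_index=s,
                    box=box,
                    difficulty=float(rng.beta(config.difficulty_alpha, config.difficulty_beta)),
                )
            )
    return GroundTruth(meta=meta, lesions=lesions)


def _jitter_box(rng: np.random.Generator, box: BoundingBox, profile: AnnotatorProfile,
                image: ImageMeta, preserve_containment: bool) -> BoundingBox:
    if profile.jitter_sd == 0 and profile.box_scale_sd == 0:
        return box
    cx, cy = box.centroid
    for _ in range(50):
        sx = float(np.exp(rng.normal(0.0, profile.box_scale_sd)))
        sy = float(np.exp(rng.normal(0.0, profile.box_scale_sd)))
        hw, hh = box.width * sx / 2.0, box.height * sy / 2.0
        noise = rng.normal(0.0, profile.jitter_sd, size=4)
        x_min = max(0.0, cx - hw + noise[0])
        y_min = max(0.0, cy - hh + noise[1])
        x_max = min(float(image.width), cx + hw + noise[2])
        y_max = min(float(image.height), cy + hh + noise[3])
        if x_min >= x_max or y_min >= y_max:
            continue
        jittered = BoundingBox(x_min, y_min, x_max, y_max)
        if not preserve_containment or centroid_match(jittered, box):
            return jittered
    return box


def simulate_annotator(
    truth: GroundTruth,
    profile: AnnotatorProfile,
    seed: int | np.random.Generator,
    session: str = "expert",
    preserve_containment: bool = True,
) -> list[Annotation]:
    """Simulate one annotator's boxes over a whole dataset.

    Each true lesion is marked with its difficulty-modulated detection
    probability and the marked box is jittered; false alarms land on
    lesion-free surfaces at ``fp_rate_per_surface``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    annotations: list[Annotation] = []
    for image in truth.meta.images:
        lesions = truth.lesions_on(image.image_id)
        occupied = {l.surface_index for l in lesions}
        for lesion in lesions:
            if rng.random() < profile.detection_prob(lesion.difficulty):
                box = _jitter_box(rng, lesion.box, profile, image, preserve_containment)
                annotations.append(
                    Annotation(image.image_id, profile.annotator_id, box, session)
                )
        if profile.fp_rate_per_surface > 0:
            n_surfaces = image.n_surfaces
            cfg = StudyConfig(
                n_images=1,
                surfaces_per_image=n_surfaces,
                image_width=image.width,
                image_height=image.height,
            )
            for s in range(n_surfaces):
                if s in occupied:
                    continue
                if rng.random() < profile.fp_rate_per_surface:
                    box = _draw_box_in_cell(rng, _surface_cell(cfg, s))
                    annotations.append(
                        Annotation(image.image_id, profile.annotator_id, box, session)
                    )
    return assign_annotation_ids(annotations)


@dataclass
class StudyBundle:
    """A complete simulated reader study, ready for the evaluation pipeline."""

    config: StudyConfig
    truth_initial: GroundTruth     # dataset annotated pre-training
    truth_testing: GroundTruth     # dataset annotated post-training
    expert_annotations: dict[str, list[Annotation]]  # dataset_id -> boxes
    student_annotations: list[Annotation]            # sessions "pre" and "post"
    roster: pd.DataFrame
    student_profiles: dict[tuple[str, str], AnnotatorProfile]  # (student, session)


def _student_ids(config: StudyConfig) -> list[tuple[str, str]]:
    out = []
    for group in sorted(config.n_students_per_group):
        for i in range(config.n_students_per_group[group]):
            out.append((f"{group}_{i + 1:02d}", group))
    return out


def simulate_study(config: StudyConfig) -> StudyBundle:
    """Generate the full study: two datasets, expert panels on both, and
    every student annotating the first dataset pre-training and the second
    post-training with the group's effect profile.

    Between-student heterogeneity: each student carries a persistent ability
    offset (Gaussian, ``ability_sd``) added to the group hit probability in
    both sessions, and a persistent log-normal multiplier on the group
    false-alarm rate — so pre/post deltas are paired within student.
    """
    truths = {
        "D0": generate_ground_truth(config, "D0", 0),
        "D1": generate_ground_truth(config, "D1", 1),
    }
    expert_annotations: dict[str, list[Annotation]] = {}
    for di, (dataset_id, truth) in enumerate(truths.items()):
        boxes: list[Annotation] = []
        for e in range(config.n_experts):
            expert_id = f"expert_{e + 1}"
            profile = replace(config.expert_profile, annotator_id=expert_id)
            rng = _stream(config.seed, 1, di, _id_key(expert_id))
            boxes.extend(
                simulate_annotator(truth, profile, rng, "expert", config.preserve_containment)
            )
        expert_annotations[dataset_id] = assign_annotation_ids(boxes)

    student_annotations: list[Annotation] = []
    roster_rows = []
    profiles: dict[tuple[str, str], AnnotatorProfile] = {}
    for k, (student_id, group) in enumerate(_student_ids(config)):
        ability_rng = _stream(config.seed, 2, _id_key(student_id))
        ability = float(ability_rng.normal(0.0, config.ability_sd))
        fp_mult = float(np.exp(ability_rng.normal(0.0, config.fp_log_sd)))
        pre_mean, post_mean = config.group_profiles[group]
        for session, mean_profile, dataset_id, di in (
            ("pre", pre_mean, "D0", 0),
            ("post", post_mean, "D1", 1),
        ):
            profile = AnnotatorProfile(
                annotator_id=student_id,
                hit_prob_majority=float(np.clip(mean_profile.hit_prob_majority + ability, 0.02, 0.99)),
                hit_prob_minority=float(np.clip(mean_profile.hit_prob_minority + ability, 0.02, 0.99)),
                fp_rate_per_surface=float(np.clip(mean_profile.fp_rate_per_surface * fp_mult, 0.0, 0.5)),
                jitter_sd=mean_profile.jitter_sd,
                box_scale_sd=mean_profile.box_scale_sd,
            )
            profiles[(student_id, session)] = profile
            rng = _stream(config.seed, 3, di, _id_key(student_id))
            student_annotations.extend(
                simulate_annotator(truths[dataset_id], profile, rng, session, config.preserve_containment)
            )
        roster_rows.append(
            {"annotator_id": student_id, "group": group, "stage": STAGES[k % len(STAGES)]}
        )
    for e in range(config.n_experts):
        roster_rows.append(
            {"annotator_id": f"expert_{e + 1}", "group": "expert", "stage": "na"}
        )

    return StudyBundle(
        config=config,
        truth_initial=truths["D0"],
        truth_testing=truths["D1"],
        expert_annotations=expert_annotations,
        student_annotations=assign_annotation_ids(student_annotations),
        roster=pd.DataFrame(roster_rows, columns=["annotator_id", "group", "stage"]),
        student_profiles=profiles,
    )


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lesion_id": l.lesion_id,
                "image_id": l.image_id,
                "surface_index": l.surface_index,
                "x_min": l.box.x_min,
                "y_min": l.box.y_min,
                "x_max": l.box.x_max,
                "y_max": l.box.y_max,
                "difficulty": l.difficulty,
            }
            for l in truth.lesions
        ]
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> None:
    """Emit the bundle as canonical CSVs: metadata, roster, expert and
    student annotations per session, and the ground truth (oracle use only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_metadata_csv(bundle.truth_initial.meta, outdir / "metadata_initial.csv")
    write_metadata_csv(bundle.truth_testing.meta, outdir / "metadata_testing.csv")
    bundle.roster.to_csv(outdir / "roster.csv", index=False)
    write_annotations_csv(bundle.expert_annotations["D0"], outdir / "annotations_experts_initial.csv")
    write_annotations_csv(bundle.expert_annotations["D1"], outdir / "annotations_experts_testing.csv")
    pre = [a for a in bundle.student_annotations if a.session == "pre"]
    post = [a for a in bundle.student_annotations if a.session == "post"]
    write_annotations_csv(pre, outdir / "annotations_students_pre.csv")
    write_annotations_csv(post, outdir / "annotations_students_post.csv")
    truth_to_frame(bundle.truth_initial).to_csv(outdir / "truth_initial.csv", index=False)
    truth_to_frame(bundle.truth_testing).to_csv(outdir / "truth_testing.csv", index=False)


def map_reference_to_truth(ref: ReferenceStandard, truth: GroundTruth) -> dict[str, TrueLesion]:
    """Associate each consensus lesion with the true lesion it arose from,
    by centroid match of the combined box against the true boxes (surfaces
    are disjoint cells, so the association is unambiguous at default noise).
    Lesions with no match are omitted."""
    mapping: dict[str, TrueLesion] = {}
    for lesion in ref.lesions:
        for true_lesion in truth.lesions_on(lesion.image_id):
            if centroid_match(lesion.combined_box, true_lesion.box):
                mapping[lesion.lesion_id] = true_lesion
                break
    return mapping


def expected_sensitivity(ref: ReferenceStandard, truth: GroundTruth, profile: AnnotatorProfile) -> float:
    """Expected measured sensitivity of a profile against the majority set:
    the mean detection probability over S lesions (via their true-lesion
    difficulties)."""
    mapping = map_reference_to_truth(ref, truth)
    probs = [
        profile.detection_prob(mapping[l.lesion_id].difficulty)
        for l in ref.lesions
        if l.set_label == "S" and l.lesion_id in mapping
    ]
    if not probs:
        raise ValueError("no majority lesions mapped to ground truth")
    return float(np.mean(probs))
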