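"""Shared fixtures: tiny hand-built datasets and reference standards."""

import pytest
from hypothesis import settings

from carieseval.consensus import build_reference
from carieseval.model import Annotation, BoundingBox, DatasetMeta, ImageMeta, assign_annotation_ids

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def box(x0, y0, x1, y1):
    return BoundingBox(x0, y0, x1, y1)


def ann(image_id, annotator_id, b, session="expert"):
    return Annotation(image_id=image_id, annotator_id=annotator_id, box=b, session=session)


def make_dataset(image_specs, dataset_id="test"):
    """image_specs: list of (image_id, width, height, n_surfaces)."""
    return DatasetMeta(
        dataset_id=dataset_id,
        images=[ImageMeta(*spec) for spec in image_specs],
    )


@pytest.fixture
def single_image_dataset():
    return make_dataset([("img0", 1000, 500, 20)])


@pytest.fixture
def fig2_reference(single_image_dataset):
    """A one-image reference standard mirroring the published worked example:
    three majority lesions (all three experts agree) and one minority lesion
    (one expert only), well separated on the image."""
    majority_centers = [(100, 100), (400, 100), (700, 100)]
    minority_center = (400, 400)
    annotations = []
    for cx, cy in majority_centers:
        for expert in ("e1", "e2", "e3"):
            annotations.append(
                ann("img0", expert, box(cx - 40, cy - 40, cx + 40, cy + 40))
            )
    cx, cy = minority_center
    annotations.append(ann("img0", "e1", box(cx - 40, cy - 40, cx + 40, cy + 40)))
    annotations = assign_annotation_ids(annotations)
    return build_reference(annotations, single_image_dataset, [])


@pytest.fixture
def fig2_candidates():
    """Six candidate boxes for the worked example: three match the majority
    lesions, one matches the minority lesion, two match nothing."""
    hits = [box(cx - 30, cy - 30, cx + 30, cy + 30) for cx, cy in
            [(100, 100), (400, 100), (700, 100), (400, 400)]]
    misses = [box(850, 300, 950, 380), box(100, 300, 200, 380)]
    return hits + misses
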