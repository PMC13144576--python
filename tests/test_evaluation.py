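"""Candidate scoring: matching stages, confusion counts, TN approximation."""

import itertools
import math

import numpy as np
import pytest

from carieseval.consensus import build_reference, centroid_match
from carieseval.evaluation import (
    ConfusionSummary,
    evaluate_dataset,
    iou,
    match_candidate,
    mean_iou,
    summarize,
)
from carieseval.model import assign_annotation_ids

from conftest import ann, box, make_dataset


class TestIoU:
    def test_identical_boxes(self):
        assert iou(box(3, 4, 10, 12), box(3, 4, 10, 12)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(0, 0, 5, 5), box(10, 10, 15, 15)) == 0.0

    def test_half_overlap(self):
        # intersection 5x10 = 50, union 100 + 100 - 50 = 150
        assert iou(box(0, 0, 10, 10), box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x0, y0, x1, y1 = rng.uniform(0, 50, 4)
            a = box(min(x0, x1), min(y0, y1), max(x0, x1) + 1, max(y0, y1) + 1)
            x0, y0, x1, y1 = rng.uniform(0, 50, 4)
            b = box(min(x0, x1), min(y0, y1), max(x0, x1) + 1, max(y0, y1) + 1)
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))


class TestMatchCandidate:
    def test_worked_example_counts(self, fig2_reference, fig2_candidates):
        """The published single-image walkthrough: 3 majority matches, 1
        tentative, 2 unmatched candidates, no missed majority lesion —
        2 errors in total."""
        result = match_candidate(fig2_candidates, fig2_reference, "img0", "student")
        assert result.tp == 3
        assert result.n_tentative == 1
        assert result.fp == 2
        assert result.fn == 0
        assert result.errors == 2

    def test_no_candidates_all_fn(self, fig2_reference):
        result = match_candidate([], fig2_reference, "img0")
        assert (result.tp, result.n_tentative, result.fp) == (0, 0, 0)
        assert result.fn == 3

    def test_identity_candidates_all_tp_iou_one(self, fig2_reference):
        boxes = [l.combined_box for l in fig2_reference.lesions_on("img0", "S")]
        result = match_candidate(boxes, fig2_reference, "img0")
        assert result.tp == len(boxes) and result.fn == 0
        assert all(score == 1.0 for *_, score in result.tp_pairs)

    def test_unknown_image_rejected(self, fig2_reference):
        with pytest.raises(KeyError):
            match_candidate([], fig2_reference, "nonexistent")

    def test_s_precedence_over_s_prime(self, single_image_dataset):
        """A candidate matching both a majority and a minority lesion is a TP."""
        annotations = assign_annotation_ids([
            ann("img0", "e1", box(100, 100, 200, 200)),
            ann("img0", "e2", box(100, 100, 200, 200)),   # majority lesion
            ann("img0", "e3", box(180, 100, 280, 200)),   # minority, adjacent
        ])
        # forbid the adjacent minority box from chaining into the majority lesion
        from carieseval.consensus import MatchOverride

        ids = [a.annotation_id for a in annotations]
        ref = build_reference(
            annotations,
            single_image_dataset,
            [MatchOverride("img0", forbidden_pairs=((ids[0], ids[2]), (ids[1], ids[2])))],
        )
        assert ref.n_majority == 1 and ref.n_minority == 1
        candidate = box(120, 100, 260, 200)  # centroid-matches both lesions
        s_box = next(l.combined_box for l in ref.lesions if l.set_label == "S")
        sp_box = next(l.combined_box for l in ref.lesions if l.set_label == "S_prime")
        assert centroid_match(candidate, s_box) and centroid_match(candidate, sp_box)
        result = match_candidate([candidate], ref, "img0")
        assert result.tp == 1 and result.n_tentative == 0

    def test_one_to_one_no_double_counting(self, single_image_dataset):
        annotations = assign_annotation_ids([
            ann("img0", "e1", box(100, 100, 200, 200)),
            ann("img0", "e2", box(100, 100, 200, 200)),
        ])
        ref = build_reference(annotations, single_image_dataset, [])
        candidates = [box(110, 110, 190, 190), box(120, 120, 180, 180)]
        result = match_candidate(candidates, ref, "img0")
        assert result.tp == 1 and result.fp == 1

    def test_monotonicity_adding_unmatched_box(self, fig2_reference, fig2_candidates):
        base = match_candidate(fig2_candidates, fig2_reference, "img0")
        extra = fig2_candidates + [box(900, 420, 990, 490)]
        more = match_candidate(extra, fig2_reference, "img0")
        assert more.fp == base.fp + 1
        assert more.errors == base.errors + 1
        assert (more.tp, more.n_tentative, more.fn) == (base.tp, base.n_tentative, base.fn)

    def test_removing_tp_box_converts_to_fn(self, fig2_reference, fig2_candidates):
        base = match_candidate(fig2_candidates, fig2_reference, "img0")
        reduced = match_candidate(fig2_candidates[1:], fig2_reference, "img0")
        assert reduced.tp == base.tp - 1
        assert reduced.fn == base.fn + 1


def brute_force_counts(candidates, s_lesions, sp_lesions):
    """Enumerate all one-to-one assignments stage by stage, maximizing pair
    count then total IoU, and return (tp, tentative, fp, fn)."""

    def best_assignment(cands, lesions):
        feasible = {
            (i, j): iou(c, l.combined_box)
            for i, c in enumerate(cands)
            for j, l in enumerate(lesions)
            if centroid_match(c, l.combined_box)
        }
        best = (0, 0.0, frozenset())
        idxs = sorted({i for i, _ in feasible})
        for r in range(min(len(cands), len(lesions)), -1, -1):
            for c_subset in itertools.combinations(idxs, r):
                for l_perm in itertools.permutations(range(len(lesions)), r):
                    pairs = list(zip(c_subset, l_perm))
                    if all(p in feasible for p in pairs):
                        total = sum(feasible[p] for p in pairs)
                        cand = (r, total, frozenset(i for i, _ in pairs))
                        if (cand[0], cand[1]) > (best[0], best[1]):
                            best = cand
            if best[0] == r and r > 0:
                break
        return best

    n_tp, _, used = best_assignment(candidates, s_lesions)
    rest = [c for i, c in enumerate(candidates) if i not in used]
    n_tent, _, _ = best_assignment(rest, sp_lesions)
    fp = len(candidates) - n_tp - n_tent
    fn = len(s_lesions) - n_tp
    return n_tp, n_tent, fp, fn


class TestAssignmentOracle:
    """The matcher must agree with brute-force enumeration of all one-to-one
    assignments (maximum pair count, then maximum total IoU) on small images."""

    @pytest.mark.parametrize("seed", range(60))
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        meta = make_dataset([("img0", 400, 400, 30)])
        n_experts_boxes = rng.integers(1, 7)
        annotations = []
        for i in range(n_experts_boxes):
            x0, y0 = rng.uniform(0, 300, 2)
            w, h = rng.uniform(40, 120, 2)
            for e in range(rng.integers(1, 4)):
                dx, dy = rng.normal(0, 8, 2)
                annotations.append(
                    ann("img0", f"e{e + 1}",
                        box(max(0, x0 + dx), max(0, y0 + dy), x0 + w + dx, y0 + h + dy))
                )
        annotations = assign_annotation_ids(annotations)
        if len({a.annotator_id for a in annotations}) < 2:
            annotations = assign_annotation_ids(
                annotations + [ann("img0", "e9", box(390, 390, 399, 399))]
            )
        ref = build_reference(annotations, meta, [])

        n_cand = rng.integers(0, 7)
        candidates = []
        for _ in range(n_cand):
            x0, y0 = rng.uniform(0, 320, 2)
            w, h = rng.uniform(30, 110, 2)
            candidates.append(box(x0, y0, x0 + w, y0 + h))

        result = match_candidate(candidates, ref, "img0")
        expected = brute_force_counts(
            candidates, ref.lesions_on("img0", "S"), ref.lesions_on("img0", "S_prime")
        )
        assert (result.tp, result.n_tentative, result.fp, result.fn) == expected


class TestSummarize:
    def _d0_meta(self):
        return make_dataset([("im0", 100, 100, 1008)], dataset_id="D0")

    def _summary_from_counts(self, tp, fp, fn, n_minority=51, total=1008):
        """Build a ConfusionSummary through the same Eq.-1 arithmetic the
        pipeline applies (used for the published-table checks)."""
        tn = total - (tp + fp + fn + n_minority)
        return ConfusionSummary("a", "pre", tp, fp, fn, tn, n_minority)

    def test_published_annotator_row_tn_and_errors(self):
        s = self._summary_from_counts(tp=116, fp=24, fn=16)
        assert s.tn == 801
        assert s.errors == 40

    def test_published_ai_row_tn_and_errors(self):
        # FP+FN = 39 regardless of which printed digit is which
        s = self._summary_from_counts(tp=103, fp=10, fn=29)
        assert s.tn == 815
        assert s.errors == 39

    def test_empty_candidates_forced_by_closure(self, fig2_reference):
        results = [match_candidate([], fig2_reference, "img0", "s")]
        s = summarize(results, fig2_reference)
        assert (s.tp, s.fp) == (0, 0)
        assert s.fn == fig2_reference.n_majority
        assert s.tn == fig2_reference.dataset.n_surfaces_total - (
            fig2_reference.n_majority + fig2_reference.n_minority
        )

    def test_closure_and_conservation(self, fig2_reference, fig2_candidates):
        results = [match_candidate(fig2_candidates, fig2_reference, "img0", "s")]
        s = summarize(results, fig2_reference)
        assert s.tp + s.fp + s.fn + s.tn + s.n_tentative_dataset == fig2_reference.dataset.n_surfaces_total
        assert s.tp + s.fn == fig2_reference.n_majority

    def test_missing_images_rejected(self, fig2_candidates):
        meta = make_dataset([("img0", 1000, 500, 20), ("img1", 1000, 500, 20)])
        annotations = assign_annotation_ids([
            ann(i, e, box(100, 100, 160, 160)) for i in ("img0", "img1") for e in ("e1", "e2")
        ])
        ref = build_reference(annotations, meta, [])
        with pytest.raises(ValueError, match="missing MatchResults.*img1"):
            summarize([match_candidate([], ref, "img0", "s")], ref)

    def test_negative_tn_rejected(self):
        meta = make_dataset([("img0", 1000, 500, 2)])
        annotations = assign_annotation_ids([
            ann("img0", "e1", box(100, 100, 160, 160)),
            ann("img0", "e2", box(100, 100, 160, 160)),
        ])
        ref = build_reference(annotations, meta, [])
        candidates = [box(x, 300, x + 50, 360) for x in range(0, 500, 100)]  # 5 FPs
        with pytest.raises(ValueError, match="negative"):
            summarize([match_candidate(candidates, ref, "img0", "s")], ref)


class TestMeanIou:
    def test_simple_mean(self):
        s = ConfusionSummary("a", "pre", 2, 0, 0, 10, 0, iou_values=[0.5, 0.5])
        assert mean_iou(s) == 0.5

    def test_pooled_mean(self):
        s = ConfusionSummary("a", "pre", 3, 0, 0, 10, 0, iou_values=[1.0, 0.0, 0.5])
        assert mean_iou(s) == 0.5

    def test_empty_is_undefined_not_zero(self):
        s = ConfusionSummary("a", "pre", 0, 0, 5, 10, 0, iou_values=[])
        assert math.isnan(mean_iou(s))


def test_evaluate_dataset_matches_manual_pipeline(fig2_reference, fig2_candidates):
    annotations = assign_annotation_ids(
        [ann("img0", "stu", b, "pre") for b in fig2_candidates]
    )
    s = evaluate_dataset(annotations, fig2_reference, "stu", "pre")
    assert (s.tp, s.fp, s.fn) == (3, 2, 0)
    assert s.errors == 2
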