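"""Candidate extraction, matching, AP/AUC and operating-point analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from lesionssl.evaluation import (DetectionMatch, ExtractionParams, average_precision,
                                  evaluate_cohort, extract_candidates,
                                  match_candidates, missed_at_fixed_fpr, patient_auc,
                                  patient_score, picai_score)

from _oracles import flood_fill_candidates, pairwise_auc, pr_table_ap


def _block_map(shape, blocks):
    """Probability map with rectangular blocks given as (slices, value)."""
    m = np.zeros(shape, np.float32)
    for sl, v in blocks:
        m[sl] = v
    return m


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_all_zero_map_yields_no_candidates(self):
        assert extract_candidates(np.zeros((8, 8, 8))) == []

    def test_single_block_candidate(self):
        m = _block_map((10, 10, 10), [((slice(2, 5), slice(2, 5), slice(2, 5)), 0.9)])
        params = ExtractionParams(threshold_fraction=0.4, min_voxels=5)
        cands = extract_candidates(m, params)
        assert len(cands) == 1
        assert cands[0].n_voxels == 27
        assert cands[0].confidence == pytest.approx(0.9)

    def test_small_component_filtered_out(self):
        m = _block_map((12, 12, 12), [
            ((slice(1, 5), slice(1, 5), slice(1, 5)), 0.8),     # 64 voxels
            ((slice(8, 9), slice(8, 11), slice(8, 9)), 0.7),    # 3 voxels
        ])
        cands = extract_candidates(m, ExtractionParams(min_voxels=5))
        assert len(cands) == 1
        assert cands[0].confidence == pytest.approx(0.8)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_maps(self, connectivity):
        params = ExtractionParams(threshold_fraction=0.4, min_voxels=4,
                                  connectivity=connectivity)
        rng = np.random.default_rng(0)
        for _ in range(40):
            m = rng.uniform(size=(16, 16, 16)).astype(np.float32)
            m[m < 0.6] = 0.0
            got = {(frozenset(map(tuple, np.argwhere(c.mask))),
                    round(c.confidence, 6)) for c in extract_candidates(m, params)}
            want = {(vox, round(conf, 6)) for vox, conf in
                    flood_fill_candidates(m, params)}
            assert got == want

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ExtractionParams(threshold_fraction=0.0)
        with pytest.raises(ValueError):
            ExtractionParams(connectivity=18)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class TestMatching:
    def _candidates_from(self, m, **kw):
        return extract_candidates(m, ExtractionParams(min_voxels=1, **kw))

    def test_identical_candidate_is_tp_with_unit_iou(self):
        gt = np.zeros((8, 8, 8), np.int16)
        gt[2:5, 2:5, 2:5] = 1
        m = (gt > 0).astype(np.float32) * 0.9
        matches = match_candidates(self._candidates_from(m), gt)
        assert len(matches) == 1
        assert matches[0].is_tp and matches[0].iou == 1.0

    def test_iou_exactly_at_threshold_is_fp(self):
        """IoU must be strictly greater than 0.10: a candidate engineered to
        exactly 0.10 counts as a false positive."""
        gt = np.zeros((4, 4, 12), np.int16)
        gt[1, 1, 0:6] = 1                      # 6 voxels
        m = np.zeros((4, 4, 12), np.float32)
        m[1, 1, 5:10] = 0.9                    # 5 voxels, overlap {5}: IoU = 1/10
        matches = match_candidates(self._candidates_from(m), gt, iou_threshold=0.10)
        assert matches[0].iou == pytest.approx(0.10)
        assert not matches[0].is_tp

    def test_iou_just_above_threshold_is_tp(self):
        gt = np.zeros((4, 4, 12), np.int16)
        gt[1, 1, 0:6] = 1
        m = np.zeros((4, 4, 12), np.float32)
        m[1, 1, 4:10] = 0.9                    # overlap {4,5}: IoU = 2/10
        matches = match_candidates(self._candidates_from(m), gt, iou_threshold=0.10)
        assert matches[0].is_tp

    def test_second_candidate_on_same_lesion_is_fp(self):
        gt = np.zeros((8, 8, 16), np.int16)
        gt[2:6, 2:6, 2:8] = 1
        m = np.zeros((8, 8, 16), np.float32)
        m[2:6, 2:6, 2:6] = 0.9                 # IoU 2/3-ish, higher confidence
        m[2:6, 2:6, 7:10] = 0.7                # overlaps the tail: lower confidence
        matches = match_candidates(self._candidates_from(m), gt)
        assert [m_.is_tp for m_ in matches] == [True, False]

    def test_tied_confidences_resolve_by_iou_then_component_id(self):
        """Two candidates with identical confidence over one lesion: the one
        with larger IoU wins the match, regardless of extraction order."""
        gt = np.zeros((6, 6, 20), np.int16)
        gt[1:4, 1:4, 1:10] = 1
        m = np.zeros((6, 6, 20), np.float32)
        m[1:4, 1:4, 1:5] = 0.8      # component 1, smaller overlap
        m[1:4, 1:4, 6:10] = 0.8     # component 2 (disjoint), same confidence
        cands = self._candidates_from(m)
        assert len(cands) == 2
        assert cands[0].confidence == cands[1].confidence
        matches = match_candidates(cands, gt)
        assert sum(mm.is_tp for mm in matches) == 1
        winner = max(matches, key=lambda mm: mm.iou)
        assert winner.is_tp

    def test_greedy_matching_agrees_with_explicit_reimplementation(self):
        """Independent assignment loop over random candidate/lesion layouts."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            gt = np.zeros((12, 12, 12), np.int16)
            for lab in (1, 2):
                z, y, x = rng.integers(0, 8, 3)
                gt[z:z + 4, y:y + 4, x:x + 4] = lab
            m = np.zeros((12, 12, 12), np.float32)
            for _ in range(3):
                z, y, x = rng.integers(0, 8, 3)
                m[z:z + 4, y:y + 4, x:x + 4] = np.maximum(
                    m[z:z + 4, y:y + 4, x:x + 4], rng.uniform(0.3, 1.0))
            cands = self._candidates_from(m)
            got = match_candidates(cands, gt)

            # oracle: same rule, written as an explicit loop over candidates
            unmatched = {int(g) for g in np.unique(gt) if g > 0}
            want = []
            for c in sorted(cands, key=lambda c: (-c.confidence, c.component_id)):
                best_g, best_iou = None, 0.0
                for g in sorted(unmatched):
                    gm = gt == g
                    inter = (c.mask & gm).sum()
                    iou = inter / (c.mask.sum() + gm.sum() - inter)
                    if iou > best_iou:
                        best_g, best_iou = g, iou
                if best_g is not None and best_iou > 0.10:
                    unmatched.discard(best_g)
                    want.append((c.component_id, True))
                else:
                    want.append((c.component_id, False))
            got_simple = [(c.component_id, mm.is_tp)
                          for mm, c in zip(got, sorted(
                              cands, key=lambda c: (-c.confidence, c.component_id)))]
            assert sorted(m_[0] for m_ in got_simple) == sorted(w[0] for w in want)
            assert [tp for _, tp in got_simple] == [tp for _, tp in want]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _match(conf, tp):
    return DetectionMatch(case_id="c", confidence=conf, matched_gt=1 if tp else None,
                          iou=1.0 if tp else 0.0, is_tp=tp)


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        assert average_precision([_match(0.9, True)], 1) == 1.0

    def test_fp_ranked_above_tp_halves_ap(self):
        assert average_precision([_match(0.9, False), _match(0.8, True)], 1) == 0.5

    def test_matches_pr_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 25))
            conf = rng.uniform(size=n)
            tp = rng.uniform(size=n) < 0.4
            n_gt = int(tp.sum() + rng.integers(1, 5))
            got = average_precision([_match(c, bool(t)) for c, t in zip(conf, tp)], n_gt)
            assert abs(got - pr_table_ap(conf, tp, n_gt)) < 1e-9

    def test_no_lesions_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            average_precision([_match(0.5, False)], 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_adding_a_false_positive_never_increases_ap(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        matches = [_match(float(c), bool(t)) for c, t in
                   zip(rng.uniform(size=n), rng.uniform(size=n) < 0.5)]
        base = average_precision(matches, 5)
        with_fp = matches + [_match(float(rng.uniform()), False)]
        assert average_precision(with_fp, 5) <= base + 1e-12

    def test_removing_a_tp_never_increases_ap(self, rng):
        matches = [_match(float(c), bool(t)) for c, t in
                   zip(rng.uniform(size=10), rng.uniform(size=10) < 0.5)]
        base = average_precision(matches, 6)
        for i, m in enumerate(matches):
            if m.is_tp:
                reduced = matches[:i] + matches[i + 1:]
                assert average_precision(reduced, 6) <= base + 1e-12

    def test_invariant_under_monotone_confidence_transform(self, rng):
        matches = [_match(float(c), bool(t)) for c, t in
                   zip(rng.uniform(size=15), rng.uniform(size=15) < 0.4)]
        warped = [_match(float(np.exp(3 * m.confidence)), m.is_tp) for m in matches]
        assert average_precision(matches, 4) == pytest.approx(
            average_precision(warped, 4), abs=1e-12)


class TestPatientMetrics:
    def test_patient_score_is_global_max(self, rng):
        m = np.zeros((6, 6, 6))
        m[3, 2, 1] = 0.73
        assert patient_score(m) == 0.73
        r = rng.uniform(size=(6, 6, 6))
        assert patient_score(r) == r.ravel().max()
        assert patient_score(np.zeros((4, 4, 4))) == 0.0
        with pytest.raises(ValueError, match="empty"):
            patient_score(np.zeros((0,)))

    def test_auc_perfect_separation(self):
        assert patient_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_auc_all_ties_is_half(self):
        assert patient_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_auc_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(20):
            scores = np.round(rng.uniform(size=12), 1)  # force some ties
            labels = rng.integers(0, 2, 12)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = patient_auc(scores, labels)
            assert abs(got - pairwise_auc(scores, labels)) < 1e-12
            assert abs(got - roc_auc_score(labels, scores)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            patient_auc([0.1, 0.2], [1, 1])

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 0, 1
        assert patient_auc(scores, labels) == pytest.approx(
            patient_auc(np.exp(5 * scores), labels), abs=1e-12)

    def test_picai_score_is_arithmetic_mean(self):
        assert picai_score(1.0, 1.0) == 1.0
        assert picai_score(0.89, 0.65) == pytest.approx(0.77)
        assert picai_score(0.86, 0.58) == pytest.approx(0.72)


class TestOperatingPoint:
    def test_perfect_classifier_misses_nothing(self):
        t, missed = missed_at_fixed_fpr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert missed == 0
        assert t < 0.8

    def test_noise_free_separation_threshold_below_positives(self):
        scores = [1.0, 1.0, 0.0, 0.0, 0.0]
        t, missed = missed_at_fixed_fpr(scores, [1, 1, 0, 0, 0], 0.5)
        assert missed == 0

    def test_matches_exhaustive_threshold_sweep(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        t, missed = missed_at_fixed_fpr(scores, labels, 0.5)
        neg = scores[labels == 0]
        pos = scores[labels == 1]
        feasible = [u for u in np.unique(scores) if (neg > u).mean() <= 0.5]
        t_oracle = min(feasible)
        assert t == t_oracle
        assert missed == (pos <= t_oracle).sum()
        assert (neg > t).mean() <= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            missed_at_fixed_fpr([0.5, 0.6], [1, 1], 0.5)


class TestCohortEvaluation:
    def test_ground_truth_maps_achieve_perfect_scores(self, annotated_cohort):
        """A predictor that outputs the ground-truth mask scores AP = AUC = 1."""
        maps = {c.case_id: (c.gt_mask > 0).astype(np.float32) for c in annotated_cohort}
        report = evaluate_cohort(maps, annotated_cohort.cases,
                                 ExtractionParams(min_voxels=1))
        assert report.auc == 1.0
        assert report.ap == 1.0
        assert report.picai == 1.0
        assert report.n_lesions == int(
            annotated_cohort.manifest["n_lesions"].astype(int).sum())

    def test_report_serializes_with_parameters(self, annotated_cohort, tmp_path):
        maps = {c.case_id: (c.gt_mask > 0).astype(np.float32) for c in annotated_cohort}
        report = evaluate_cohort(maps, annotated_cohort.cases,
                                 ExtractionParams(min_voxels=1))
        path = report.save(tmp_path / "report.json")
        import json
        d = json.loads(path.read_text())
        assert d["extraction"]["min_voxels"] == 1
        assert len(d["per_case"]) == len(annotated_cohort.cases)
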