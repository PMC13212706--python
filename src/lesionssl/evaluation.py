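"""Lesion-candidate extraction and detection/diagnosis metrics.

Probability maps are post-processed into discrete lesion candidates with a
per-case dynamic threshold (a fixed fraction of the case maximum), 3D
connected-component analysis, and a minimum component size.  Each
candidate's confidence is the maximum probability inside its component.
Candidates count as true positives when their intersection-over-union with
an unmatched ground-truth lesion strictly exceeds 0.10; matching is greedy
in descending confidence and one-to-one per ground-truth lesion.

Cohort metrics:

* lesion-level **AP** — non-interpolated area under the precision-recall
  curve over all pooled ranked detections;
* patient-level **AUC** — ROC area with each case scored by its maximum
  voxel probability (Mann-Whitney form, ties counted 1/2);
* the **PI-CAI score** — the arithmetic mean of the two;
* a fixed-FPR operating point (default 0.50) with the count of missed
  positive cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata


@dataclass(frozen=True)
class ExtractionParams:
    """Candidate-extraction settings, recorded in every metric report."""

    threshold_fraction: float = 0.4
    min_voxels: int = 10
    connectivity: int = 26

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be a positive integer")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


@dataclass(eq=False)  # identity semantics: candidates hold voxel arrays
class LesionCandidate:
    """One connected prediction component."""

    case_id: str
    mask: np.ndarray  # boolean voxel set
    confidence: float
    component_id: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DetectionMatch:
    """A candidate's classification against the ground truth of its case."""

    case_id: str
    confidence: float
    matched_gt: int | None
    iou: float
    is_tp: bool


def extract_candidates(prob_map: np.ndarray, params: ExtractionParams | None = None,
                       case_id: str = "") -> list:
    """Extract lesion candidates from one probability map.

    Threshold at ``threshold_fraction * max(map)``, label connected
    components under the declared connectivity, drop components smaller than
    ``min_voxels``, score each by its maximum probability.  Returned sorted
    by confidence descending (ties by component id).  An all-zero map yields
    an empty list.
    """
    params = params if params is not None else ExtractionParams()
    prob_map = np.asarray(prob_map)
    vmax = float(prob_map.max(initial=0.0))
    if vmax <= 0.0:
        return []
    binm = prob_map >= params.threshold_fraction * vmax
    labels, n = ndimage.label(binm, structure=params.structure)
    candidates = []
    for comp in range(1, n + 1):
        mask = labels == comp
        size = int(mask.sum())
        if size < params.min_voxels:
            continue
        candidates.append(LesionCandidate(
            case_id=case_id, mask=mask,
            confidence=float(prob_map[mask].max()), component_id=comp))
    candidates.sort(key=lambda c: (-c.confidence, c.component_id))
    return candidates


def fallback_component(prob_map: np.ndarray) -> np.ndarray | None:
    """Largest connected component above half the map maximum (pseudo-label fallback)."""
    prob_map = np.asarray(prob_map)
    vmax = float(prob_map.max(initial=0.0))
    if vmax <= 0.0:
        return None
    labels, n = ndimage.label(prob_map >= 0.5 * vmax,
                              structure=ndimage.generate_binary_structure(3, 3))
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def match_candidates(candidates, gt_mask: np.ndarray,
                     iou_threshold: float = 0.10) -> list:
    """Greedy confidence-ordered one-to-one matching against ground-truth lesions.

    Each candidate claims the unmatched ground-truth lesion of highest IoU
    if that IoU strictly exceeds the threshold; otherwise it is a false
    positive.  Candidates with identical confidence are tie-broken by larger
    best-IoU, then lower component id.
    """
    gt_mask = np.asarray(gt_mask)
    gt_ids = [int(g) for g in np.unique(gt_mask) if g > 0]
    gt_masks = {g: gt_mask == g for g in gt_ids}
    matched: set = set()
    matches = []

    remaining = list(candidates)
    while remaining:
        top_conf = max(c.confidence for c in remaining)
        tied = [c for c in remaining if c.confidence == top_conf]
        best = {}
        for c in tied:
            ious = {g: _iou(c.mask, gt_masks[g]) for g in gt_ids if g not in matched}
            if ious:
                g_best = max(ious, key=lambda g: (ious[g], -g))
                best[c.component_id] = (g_best, ious[g_best])
            else:
                best[c.component_id] = (None, 0.0)
        tied.sort(key=lambda c: (-best[c.component_id][1], c.component_id))
        c = tied[0]
        g_best, iou = best[c.component_id]
        if g_best is not None and iou > iou_threshold:
            matched.add(g_best)
            matches.append(DetectionMatch(c.case_id, c.confidence, g_best, iou, True))
        else:
            matches.append(DetectionMatch(c.case_id, c.confidence,
                                          None, iou, False))
        remaining.remove(c)
    return matches


def average_precision(matches, n_gt_lesions: int) -> float:
    """Non-interpolated AP over the pooled ranked detection list.

    ``AP = sum_n (R_n - R_{n-1}) * P_n`` with detections ranked by
    confidence descending; 0 if the list contains no true positive.
    """
    if n_gt_lesions < 1:
        raise ValueError("average precision is undefined without ground-truth lesions")
    ordered = sorted(matches, key=lambda m: -m.confidence)
    tp = 0
    ap = 0.0
    prev_recall = 0.0
    for rank, m in enumerate(ordered, start=1):
        if m.is_tp:
            tp += 1
            recall = tp / n_gt_lesions
            precision = tp / rank
            ap += (recall - prev_recall) * precision
            prev_recall = recall
    return float(ap)


def patient_score(prob_map: np.ndarray) -> float:
    """Case-level likelihood of disease: the global maximum voxel probability."""
    prob_map = np.asarray(prob_map)
    if prob_map.size == 0:
        raise ValueError("empty probability map")
    return float(prob_map.max())


def patient_auc(scores, labels) -> float:
    """ROC AUC as the normalised Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("patient AUC requires both positive and negative cases")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def picai_score(auc: float, ap: float) -> float:
    """Overall score: the arithmetic mean of patient AUC and lesion AP."""
    return (auc + ap) / 2.0


def missed_at_fixed_fpr(scores, labels, target_fpr: float = 0.50):
    """Operating point at a fixed false-positive rate.

    The threshold is the smallest observed score whose exceedance FPR
    (``mean(negatives > t)``, strict) does not exceed ``target_fpr``; a case
    is called positive when its score strictly exceeds the threshold, so the
    achieved FPR never exceeds the target.  Returns ``(threshold,
    n_missed_positives)`` where missed positives have score <= threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("fixed-FPR analysis requires both classes")
    for t in np.unique(scores):
        if (neg > t).mean() <= target_fpr:
            return float(t), int((pos <= t).sum())
    t = float(scores.max())
    return t, int((pos <= t).sum())


# ---------------------------------------------------------------------------
# cohort-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Cohort evaluation: diagnosis + detection metrics and their inputs."""

    auc: float
    ap: float
    picai: float
    n_cases: int
    n_lesions: int
    iou_threshold: float
    extraction: ExtractionParams
    per_case: pd.DataFrame = field(repr=False)
    matches: list = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ap": self.ap, "picai_score": self.picai,
            "n_cases": self.n_cases, "n_lesions": self.n_lesions,
            "iou_threshold": self.iou_threshold,
            "extraction": {"threshold_fraction": self.extraction.threshold_fraction,
                           "min_voxels": self.extraction.min_voxels,
                           "connectivity": self.extraction.connectivity},
            "per_case": self.per_case.to_dict(orient="records"),
            "detections": [
                {"case_id": m.case_id, "confidence": m.confidence,
                 "is_tp": bool(m.is_tp), "iou": m.iou} for m in self.matches],
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def evaluate_cohort(prob_maps: dict, cases, params: ExtractionParams | None = None,
                    iou_threshold: float = 0.10) -> MetricReport:
    """Full evaluation of a predictor on an annotated cohort.

    ``prob_maps`` maps case_id to a probability map aligned with the case
    grid; every case needs a ground-truth mask (or must be negative).
    """
    params = params if params is not None else ExtractionParams()
    rows, all_matches = [], []
    n_lesions = 0
    for case in cases:
        prob = np.asarray(prob_maps[case.case_id])
        if prob.shape != case.grid_shape:
            raise ValueError(f"prediction for {case.case_id} has shape {prob.shape}, "
                             f"expected {case.grid_shape}")
        gt = case.gt_mask if case.gt_mask is not None else np.zeros(case.grid_shape,
                                                                   dtype=np.int16)
        if case.case_positive and not gt.any():
            raise ValueError(f"positive case {case.case_id} has no ground-truth mask; "
                             "evaluate on a fully annotated cohort")
        candidates = extract_candidates(prob, params, case_id=case.case_id)
        matches = match_candidates(candidates, gt, iou_threshold)
        all_matches.extend(matches)
        n_lesions += int(gt.max())
        rows.append({"case_id": case.case_id,
                     "score": patient_score(prob),
                     "label": int(case.case_positive),
                     "n_candidates": len(candidates),
                     "n_gt_lesions": int(gt.max()),
                     "n_tp": sum(m.is_tp for m in matches)})
    per_case = pd.DataFrame(rows)
    auc = patient_auc(per_case["score"], per_case["label"])
    ap = average_precision(all_matches, n_lesions)
    return MetricReport(auc=auc, ap=ap, picai=picai_score(auc, ap),
                        n_cases=len(rows), n_lesions=n_lesions,
                        iou_threshold=iou_threshold, extraction=params,
                        per_case=per_case, matches=all_matches)
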