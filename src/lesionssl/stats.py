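"""Statistical comparison of paired detection models.

Implements the comparison stack used to judge whether two models evaluated
on the *same* cohort differ: percentile bootstrap confidence intervals
(case-level resampling, n-out-of-n), the fast DeLong test for the difference
of correlated ROC AUCs (midrank form), a paired bootstrap test for the
difference in lesion-level average precision, and Holm-Bonferroni step-down
adjustment across the tested family.

All resampling is deterministic given a seed.  Resamples on which a metric
is undefined (e.g. a single-class draw for AUC, a lesion-free draw for AP)
are redrawn so that every reported interval and p-value rests on the full
number of effective replicates; an abort is raised if more than half of all
attempted resamples are undefined.  Bootstrap p-values are floored at 1/B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .evaluation import patient_auc

log = logging.getLogger("lesionssl")


# ---------------------------------------------------------------------------
# paired results container
# ---------------------------------------------------------------------------

@dataclass
class PairedModelResults:
    """Per-case outputs of two models on one cohort (paired design).

    ``matches_a``/``matches_b`` hold, per case, the ranked detections as
    ``(confidence, is_tp)`` pairs; ``n_gt`` the ground-truth lesion count
    per case.
    """

    case_ids: list
    labels: np.ndarray
    scores_a: np.ndarray
    scores_b: np.ndarray
    matches_a: list
    matches_b: list
    n_gt: np.ndarray

    def __post_init__(self):
        n = len(self.case_ids)
        self.labels = np.asarray(self.labels).astype(int)
        self.scores_a = np.asarray(self.scores_a, dtype=np.float64)
        self.scores_b = np.asarray(self.scores_b, dtype=np.float64)
        self.n_gt = np.asarray(self.n_gt).astype(int)
        for name in ("labels", "scores_a", "scores_b", "matches_a", "matches_b", "n_gt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the {n} case ids")

    @classmethod
    def from_reports(cls, report_a, report_b) -> "PairedModelResults":
        """Pair two :class:`~lesionssl.evaluation.MetricReport` objects."""
        pa, pb = report_a.per_case, report_b.per_case
        if list(pa["case_id"]) != list(pb["case_id"]):
            raise ValueError("reports cover different or differently ordered cases")

        def group(report):
            by_case = {cid: [] for cid in report.per_case["case_id"]}
            for m in report.matches:
                by_case[m.case_id].append((float(m.confidence), bool(m.is_tp)))
            return [by_case[cid] for cid in report.per_case["case_id"]]

        return cls(case_ids=list(pa["case_id"]), labels=pa["label"].to_numpy(),
                   scores_a=pa["score"].to_numpy(), scores_b=pb["score"].to_numpy(),
                   matches_a=group(report_a), matches_b=group(report_b),
                   n_gt=pa["n_gt_lesions"].to_numpy())


@dataclass
class ComparisonReport:
    """One metric's paired comparison between models A and B."""

    metric: str
    estimate_a: float
    estimate_b: float
    ci_a: tuple
    ci_b: tuple
    p_raw: float
    p_adjusted: float
    test_name: str
    n_bootstrap: int
    seed: int

    def __post_init__(self):
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p-value cannot be below the raw p-value")
        for ci in (self.ci_a, self.ci_b):
            if ci[0] > ci[1]:
                raise ValueError(f"CI bounds out of order: {ci}")


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def bootstrap_ci(metric, n_cases: int, n_bootstrap: int = 10000, seed: int = 0,
                 alpha: float = 0.05):
    """Percentile bootstrap CI for a per-case metric functional.

    ``metric(indices)`` receives an integer resample (with replacement,
    n-out-of-n) and returns the metric value, raising ``ValueError`` when the
    draw leaves it undefined; such draws are redrawn.  Returns the
    ``(alpha/2, 1 - alpha/2)`` percentile bounds.
    """
    rng = np.random.default_rng(seed)
    values = np.empty(n_bootstrap)
    got, failures, attempts = 0, 0, 0
    while got < n_bootstrap:
        idx = rng.integers(0, n_cases, n_cases)
        attempts += 1
        try:
            values[got] = metric(idx)
            got += 1
        except ValueError:
            failures += 1
            if attempts >= 20 and failures > attempts / 2:
                raise RuntimeError(
                    f"metric undefined on {failures}/{attempts} bootstrap "
                    "resamples (> 50%); the cohort is too small or too "
                    "unbalanced for a bootstrap CI")
    if failures:
        log.info("bootstrap_ci: redrew %d undefined resamples (of %d attempts)",
                 failures, attempts)
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _ap_pooled(conf: np.ndarray, tp: np.ndarray, n_gt: int) -> float:
    """Array-form non-interpolated AP (same definition as evaluation.average_precision)."""
    if n_gt < 1:
        raise ValueError("AP undefined without ground-truth lesions")
    if len(conf) == 0:
        return 0.0
    order = np.argsort(-conf, kind="stable")
    tp_sorted = tp[order].astype(np.float64)
    cum_tp = np.cumsum(tp_sorted)
    ranks = np.arange(1, len(conf) + 1)
    precision = cum_tp / ranks
    return float((precision * tp_sorted).sum() / n_gt)


def _case_arrays(matches) -> list:
    out = []
    for case_matches in matches:
        if case_matches:
            conf = np.array([c for c, _ in case_matches], dtype=np.float64)
            tp = np.array([t for _, t in case_matches], dtype=bool)
        else:
            conf = np.empty(0)
            tp = np.empty(0, dtype=bool)
        out.append((conf, tp))
    return out


def cohort_ap(matches, n_gt) -> float:
    """AP over a cohort given per-case ``(confidence, is_tp)`` lists."""
    arrays = _case_arrays(matches)
    conf = np.concatenate([a[0] for a in arrays]) if arrays else np.empty(0)
    tp = np.concatenate([a[1] for a in arrays]) if arrays else np.empty(0, dtype=bool)
    return _ap_pooled(conf, tp, int(np.sum(n_gt)))


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1  # average 1-based rank of the tie group
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray):
    """AUCs and their DeLong covariance matrix for k models on paired data.

    ``scores`` has shape (k, n); positives are ``labels == 1``.  Uses the
    midrank (structural-component) formulation: placement values per class,
    whose sample covariances scaled by class sizes estimate the covariance
    of the paired AUC estimators.
    """
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong requires both classes")
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        x, y = scores[r][pos], scores[r][~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Identical score vectors (zero variance of the difference) report a
    difference of 0 with p = 1.
    """
    scores = np.vstack([np.asarray(scores_a, dtype=np.float64),
                        np.asarray(scores_b, dtype=np.float64)])
    aucs, cov = delong_auc_variance(scores, labels)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or np.isclose(var_diff, 0.0, atol=1e-15):
        if np.isclose(aucs[0], aucs[1]):
            return DelongResult(float(aucs[0]), float(aucs[1]), 0.0, 1.0)
        var_diff = max(var_diff, 1e-15)
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    p = 2.0 * norm.sf(abs(z))
    return DelongResult(float(aucs[0]), float(aucs[1]), float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# bootstrap AP test
# ---------------------------------------------------------------------------

def ap_bootstrap_test(results: PairedModelResults, n_bootstrap: int = 10000,
                      seed: int = 0) -> float:
    """Paired bootstrap test for the AP difference between models A and B.

    Cases are resampled with replacement; per replicate the pooled AP of
    each model is recomputed on the same resample and the difference
    recorded.  ``p = 2 * min(frac <= 0, frac >= 0)`` clipped to
    ``[1/B, 1]``.  Lesion-free resamples are redrawn; a cohort with no
    lesions at all is an error.
    """
    if int(results.n_gt.sum()) == 0:
        raise ValueError("bootstrap AP test requires a cohort with lesions")
    arrays_a = _case_arrays(results.matches_a)
    arrays_b = _case_arrays(results.matches_b)
    n = len(results.case_ids)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_bootstrap)
    got = 0
    while got < n_bootstrap:
        idx = rng.integers(0, n, n)
        n_gt = int(results.n_gt[idx].sum())
        if n_gt == 0:
            continue
        conf_a = np.concatenate([arrays_a[i][0] for i in idx])
        tp_a = np.concatenate([arrays_a[i][1] for i in idx])
        conf_b = np.concatenate([arrays_b[i][0] for i in idx])
        tp_b = np.concatenate([arrays_b[i][1] for i in idx])
        diffs[got] = _ap_pooled(conf_a, tp_a, n_gt) - _ap_pooled(conf_b, tp_b, n_gt)
        got += 1
    frac_le = float((diffs <= 0).mean())
    frac_ge = float((diffs >= 0).mean())
    p = 2.0 * min(frac_le, frac_ge)
    return float(np.clip(p, 1.0 / n_bootstrap, 1.0))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    ``adjusted_(i) = max_{j <= i} (m - j + 1) * p_(j)`` over the ascending
    order statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D array of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# end-to-end comparison
# ---------------------------------------------------------------------------

def compare_models(results: PairedModelResults, n_bootstrap: int = 10000,
                   seed: int = 0) -> list:
    """Full paired comparison: AUC (DeLong) and AP (bootstrap), Holm-adjusted.

    Returns one :class:`ComparisonReport` per metric; the Holm family is the
    set of tests performed by this call.
    """
    labels = results.labels

    def auc_metric(scores):
        def f(idx):
            return patient_auc(scores[idx], labels[idx])
        return f

    def ap_metric(arrays):
        def f(idx):
            n_gt = int(results.n_gt[idx].sum())
            conf = np.concatenate([arrays[i][0] for i in idx])
            tp = np.concatenate([arrays[i][1] for i in idx])
            return _ap_pooled(conf, tp, n_gt)
        return f

    n = len(results.case_ids)
    dl = delong_test(results.scores_a, results.scores_b, labels)
    p_ap = ap_bootstrap_test(results, n_bootstrap=n_bootstrap, seed=seed + 1)
    adj = holm_bonferroni([dl.p, p_ap])

    arrays_a = _case_arrays(results.matches_a)
    arrays_b = _case_arrays(results.matches_b)
    reports = [
        ComparisonReport(
            metric="patient_auc", estimate_a=dl.auc_a, estimate_b=dl.auc_b,
            ci_a=bootstrap_ci(auc_metric(results.scores_a), n, n_bootstrap, seed + 2),
            ci_b=bootstrap_ci(auc_metric(results.scores_b), n, n_bootstrap, seed + 3),
            p_raw=dl.p, p_adjusted=float(adj[0]), test_name="delong",
            n_bootstrap=n_bootstrap, seed=seed),
        ComparisonReport(
            metric="lesion_ap",
            estimate_a=cohort_ap(results.matches_a, results.n_gt),
            estimate_b=cohort_ap(results.matches_b, results.n_gt),
            ci_a=bootstrap_ci(ap_metric(arrays_a), n, n_bootstrap, seed + 4),
            ci_b=bootstrap_ci(ap_metric(arrays_b), n, n_bootstrap, seed + 5),
            p_raw=p_ap, p_adjusted=float(adj[1]), test_name="bootstrap_ap",
            n_bootstrap=n_bootstrap, seed=seed),
    ]
    return reports
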