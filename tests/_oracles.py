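"""Independent brute-force oracles shared by the test modules.

Each function re-derives a quantity by the most literal method available
(BFS flood fill, explicit PR tables, exhaustive pairwise comparison,
delete-one jackknife) and is kept free of any package internals beyond the
public metric being checked.
"""

import numpy as np


def flood_fill_candidates(prob_map, params):
    """BFS flood fill + size filter + max-confidence scoring."""
    vmax = prob_map.max()
    if vmax <= 0:
        return []
    binm = prob_map >= params.threshold_fraction * vmax
    if params.connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                 for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    seen = np.zeros(binm.shape, bool)
    comps = []
    for idx in np.argwhere(binm):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], []
        seen[idx] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in neigh:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < binm.shape[i] for i in range(3)) \
                        and binm[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if len(comp) >= params.min_voxels:
            comps.append((frozenset(comp), max(float(prob_map[v]) for v in comp)))
    return comps


def pr_table_ap(confidences, is_tp, n_gt):
    """AP by explicit enumeration of the precision-recall table."""
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.asarray(is_tp)[order]
    ap, prev_r, n_tp = 0.0, 0.0, 0
    for rank, hit in enumerate(tp, start=1):
        if hit:
            n_tp += 1
            r = n_tp / n_gt
            ap += (r - prev_r) * (n_tp / rank)
            prev_r = r
    return ap


def pairwise_auc(scores, labels):
    """Mann-Whitney AUC by exhaustive pairwise comparison, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def jackknife_var_auc(scores, labels, auc_fn):
    """Delete-one jackknife variance of an AUC functional, one class at a time."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    var = 0.0
    for cls in (1, 0):
        idx = np.where(labels == cls)[0]
        n = len(idx)
        reduced = []
        for i in idx:
            keep = np.ones(len(scores), bool)
            keep[i] = False
            reduced.append(auc_fn(scores[keep], labels[keep]))
        reduced = np.asarray(reduced)
        var += (n - 1) / n * np.sum((reduced - reduced.mean()) ** 2)
    return var


def jackknife_var_auc_difference(sa, sb, labels, auc_fn):
    """Delete-one jackknife variance of the paired AUC difference."""
    sa, sb = np.asarray(sa, float), np.asarray(sb, float)
    labels = np.asarray(labels).astype(int)
    var = 0.0
    for cls in (1, 0):
        idx = np.where(labels == cls)[0]
        n = len(idx)
        reduced = []
        for i in idx:
            keep = np.ones(len(sa), bool)
            keep[i] = False
            reduced.append(auc_fn(sa[keep], labels[keep])
                           - auc_fn(sb[keep], labels[keep]))
        reduced = np.asarray(reduced)
        var += (n - 1) / n * np.sum((reduced - reduced.mean()) ** 2)
    return var
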