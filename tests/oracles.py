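"""Independent brute-force oracles used to cross-check the evaluation and
fitting code. Deliberately naive: pairwise counting for the AUC, exhaustive
threshold scans for Youden's J, per-record counting for confusion tables,
and fine-grid scans of the mean-probability curve for the calibration roots.
They share no code with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def auc_pair_count(scores, labels) -> float:
    """Mann-Whitney statistic by explicit pair enumeration (+1/2 per tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_by_counting(scores, labels, threshold):
    """(tp, tn, fp, fn) under the rule score >= threshold, one record at a time."""
    tp = tn = fp = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= threshold
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 1:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def youden_scan(scores, labels):
    """Exhaustive Youden scan over observed-score thresholds.

    Returns (threshold, J) after applying the tie-break order: maximal J,
    then maximal sensitivity, then smallest threshold.
    """
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best = None
    for t in sorted(set(scores)):
        tp, tn, fp, fn = confusion_by_counting(scores, labels, t)
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, j)
    return best[1], best[2]


def qn_grid_scan(diameters, target, z=1.0, q_max=1.0, step=1e-7):
    """Fine-grid root of mean(1 - exp(-Q d^z)) = target, scanned in chunks."""
    d_pow = np.asarray(diameters, dtype=float) ** z
    grid = np.arange(step, q_max, step)
    best_q, best_err = None, np.inf
    for chunk in np.array_split(grid, max(1, grid.size // 200_000)):
        means = np.mean(-np.expm1(-np.outer(chunk, d_pow)), axis=1)
        errs = np.abs(means - target)
        i = int(np.argmin(errs))
        if errs[i] < best_err:
            best_q, best_err = float(chunk[i]), float(errs[i])
        if means[-1] > target:  # curve is increasing; no need to scan further
            break
    return best_q


def g_grid_scan(diameters, rate, qn, z=1.0, g_max=50.0, step=1e-6):
    """Fine-grid root of mean(1 - exp(-qn g d^z)) = rate."""
    d_pow = np.asarray(diameters, dtype=float) ** z
    grid = np.arange(step, g_max, step)
    best_g, best_err = None, np.inf
    for chunk in np.array_split(grid, max(1, grid.size // 200_000)):
        means = np.mean(-np.expm1(-qn * np.outer(chunk, d_pow)), axis=1)
        errs = np.abs(means - rate)
        i = int(np.argmin(errs))
        if errs[i] < best_err:
            best_g, best_err = float(chunk[i]), float(errs[i])
        if means[-1] > rate:
            break
    return best_g
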