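"""Performance protocol: ROC/AUC, Youden cut-point, hold-out split,
repeated stratified k-fold cross-validation and clinical subgroup reports.

The classification rule everywhere is ``score >= threshold -> positive``.
The Youden cut-point maximizes J(t) = sensitivity(t) + specificity(t) - 1
over the observed scores; ties in J are broken toward higher sensitivity
(favoring fewer missed positive nodes), then toward the smaller threshold.

Cross-validation runs ``n_rounds`` independent rounds of class-stratified
k-fold partitioning; within a round every record is scored exactly once by a
model fitted on the other folds, the out-of-fold scores are pooled, and one
AUC / accuracy / sensitivity / specificity quadruple is computed per round at
that round's pooled Youden threshold. Round metrics are summarized by median
and quartiles (linear interpolation between order statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import FactorScheme, PatientRecord, Subtype, assign_subtype
from .errors import DegenerateCohortError
from .model import CohortMatrix
from .training import DEFAULT_MIN_STRATUM, fit_model_matrix


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    """Threshold-based metrics; ``auc`` is None when not computed."""

    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts
    auc: float | None = None


@dataclass(frozen=True)
class Quartiles:
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class CVSummary:
    auc: Quartiles
    accuracy: Quartiles
    sensitivity: Quartiles
    specificity: Quartiles
    n_rounds: int
    n_folds: int
    base_seed: int
    round_seeds: tuple[int, ...]


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise DegenerateCohortError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the empirical ROC curve.

    Equals the Mann–Whitney probability P(score_pos > score_neg) + half the
    tie probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Cut-point maximizing Youden's J over the observed scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    uniq, first_idx = np.unique(s_sorted, return_index=True)
    # counts strictly below each candidate threshold (rule: score >= t -> positive)
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(1 - y_sorted)])
    pos_below = cum_pos[first_idx]
    neg_below = cum_neg[first_idx]
    sens = (n_pos - pos_below) / n_pos
    spec = neg_below / n_neg
    j = sens + spec - 1.0

    best = j.max()
    cand = np.flatnonzero(j == best)
    cand = cand[sens[cand] == sens[cand].max()]
    return float(uniq[cand.min()])


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> EvalMetrics:
    """Accuracy / sensitivity / specificity at the rule ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return EvalMetrics(
        threshold=float(threshold),
        accuracy=(tp + tn) / counts.total,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        counts=counts,
    )


def evaluate_scores(scores: Sequence[float], labels: Sequence[int],
                    threshold: float | None = None) -> EvalMetrics:
    """AUC plus threshold metrics; Youden-selected threshold when none given."""
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    m = confusion_metrics(scores, labels, threshold)
    return EvalMetrics(threshold=m.threshold, accuracy=m.accuracy,
                       sensitivity=m.sensitivity, specificity=m.specificity,
                       counts=m.counts, auc=roc_auc(scores, labels))


def holdout_split(
    cohort: Sequence[PatientRecord], fraction: float, seed: int
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Simple random train/test partition; training size is ceil(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(cohort)
    n_train = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [cohort[i] for i in sorted(perm[:n_train])]
    test = [cohort[i] for i in sorted(perm[n_train:])]
    import logging

    logger = logging.getLogger(__name__)
    for name, part in (("train", train), ("test", test)):
        pos = sum(r.node_status for r in part)
        logger.info("holdout %s: n=%d, positives=%d, negatives=%d",
                    name, len(part), pos, len(part) - pos)
        if part and pos in (0, len(part)):
            logger.warning("holdout %s partition is single-class; fitting will fail", name)
    return train, test


def repeated_cv(
    cohort: Sequence[PatientRecord],
    scheme: FactorScheme,
    z: float = 1.0,
    n_rounds: int = 100,
    n_folds: int = 10,
    base_seed: int = 0,
    min_stratum: int = DEFAULT_MIN_STRATUM,
) -> CVSummary:
    """Repeated class-stratified k-fold cross-validation of the fitted model."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    matrix = CohortMatrix(cohort, scheme)
    y = matrix.labels
    _check_two_classes(y)
    minority = min(int(y.sum()), int(y.size - y.sum()))
    if minority < n_folds:
        raise DegenerateCohortError(
            f"minority class has {minority} records (< {n_folds} folds); use fewer folds"
        )
    round_seeds = tuple(base_seed + r for r in range(n_rounds))
    aucs, accs, sens, specs = [], [], [], []
    for seed in round_seeds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        oof = np.full(matrix.n, np.nan)
        for train_idx, test_idx in splitter.split(np.zeros(matrix.n), y):
            report = fit_model_matrix(matrix.subset(train_idx), z=z, min_stratum=min_stratum)
            oof[test_idx] = matrix.subset(test_idx).predict(report.params)
        assert not np.isnan(oof).any(), "every record must be scored exactly once per round"
        m = evaluate_scores(oof, y)
        aucs.append(m.auc)
        accs.append(m.accuracy)
        sens.append(m.sensitivity)
        specs.append(m.specificity)

    def q(vals: list[float]) -> Quartiles:
        med, q1, q3 = np.percentile(vals, [50, 25, 75])
        return Quartiles(median=float(med), q1=float(q1), q3=float(q3))

    return CVSummary(auc=q(aucs), accuracy=q(accs), sensitivity=q(sens),
                     specificity=q(specs), n_rounds=n_rounds, n_folds=n_folds,
                     base_seed=base_seed, round_seeds=round_seeds)


# --------------------------------------------------------------------------
# Clinical subgroup stratification
# --------------------------------------------------------------------------

StratumDef = tuple[str, Callable[[PatientRecord], bool]]


def default_strata() -> list[StratumDef]:
    """Clinically conventional subgroups: overall, tumor size, age bands,
    grade, and St. Gallen molecular subtype."""
    return [
        ("overall", lambda r: True),
        ("T1", lambda r: r.diameter <= 20),
        ("T2", lambda r: 20 < r.diameter <= 50),
        ("age<=45", lambda r: r.age <= 45),
        ("45<age<=60", lambda r: 45 < r.age <= 60),
        ("age>60", lambda r: r.age > 60),
        ("G1", lambda r: r.grading == "1"),
        ("G2", lambda r: r.grading == "2"),
        ("G3", lambda r: r.grading == "3"),
        ("LuminalA", lambda r: assign_subtype(r) is Subtype.LUMINAL_A),
        ("LuminalB", lambda r: assign_subtype(r) is Subtype.LUMINAL_B),
        ("HER2pos", lambda r: assign_subtype(r) is Subtype.HER2_POS),
        ("TripleNegative", lambda r: assign_subtype(r) is Subtype.TRIPLE_NEGATIVE),
    ]


def stratified_performance(
    cohort: Sequence[PatientRecord],
    scores: Sequence[float],
    threshold: float,
    strata: Sequence[StratumDef] | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity per subgroup at a fixed, upstream-chosen threshold.

    The threshold is never re-optimized per stratum. Subgroups with no
    positives report sensitivity as NaN; likewise specificity with no
    negatives. Columns: stratum, n, n_pos, sensitivity, specificity.
    """
    if len(scores) != len(cohort):
        raise ValueError("scores must align with the cohort")
    if strata is None:
        strata = default_strata()
    scores = np.asarray(scores, dtype=float)
    labels = np.array([r.node_status for r in cohort], dtype=int)
    pred = scores >= threshold
    rows = []
    for name, predicate in strata:
        mask = np.array([predicate(r) for r in cohort], dtype=bool)
        n = int(mask.sum())
        pos = labels[mask] == 1
        n_pos = int(pos.sum())
        n_neg = n - n_pos
        tp = int(np.sum(pred[mask] & pos))
        tn = int(np.sum(~pred[mask] & ~pos))
        rows.append(
            {
                "stratum": name,
                "n": n,
                "n_pos": n_pos,
                "sensitivity": tp / n_pos if n_pos else float("nan"),
                "specificity": tn / n_neg if n_neg else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "n", "n_pos", "sensitivity", "specificity"])
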