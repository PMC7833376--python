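"""Evaluation protocol: AUC and Youden against brute-force oracles, confusion
identities, hold-out splitting, repeated cross-validation contracts, and
subgroup stratification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from slncalc.cohort import build_scheme
from slncalc.errors import DegenerateCohortError
from slncalc.evaluation import (
    confusion_metrics,
    holdout_split,
    repeated_cv,
    roc_auc,
    stratified_performance,
    youden_threshold,
)
from slncalc.simulate import default_config, generate_cohort
from tests.oracles import auc_pair_count, confusion_by_counting, youden_scan
from tests.test_cohort import make_record


def random_instance(rng, n_max=100):
    n = int(rng.integers(4, n_max + 1))
    scores = rng.choice(np.round(rng.random(20), 2), size=n)  # force some ties
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores.tolist(), labels.tolist()


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_concordance_example(self):
        # 2 of 4 pos-neg pairs concordant
        assert roc_auc([0.9, 0.6, 0.4, 0.2], [1, 0, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_pairwise_oracle(self, seed):
        scores, labels = random_instance(np.random.default_rng(seed))
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_count(scores, labels), abs=1e-12
        )

    @given(st.integers(0, 10_000))
    def test_invariant_under_increasing_transform(self, seed):
        scores, labels = random_instance(np.random.default_rng(seed))
        transformed = [2.0 * s**3 + 0.5 for s in scores]
        assert roc_auc(transformed, labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_symmetry_without_ties(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(0.01, 0.99, 30)).tolist()
        labels = rng.integers(0, 2, 30).tolist()
        labels[0] = 1 - labels[1]
        neg = [-s for s in scores]
        assert roc_auc(scores, labels) + roc_auc(neg, labels) == pytest.approx(1.0)


class TestYoudenThreshold:
    def test_perfect_separation_returns_smallest_positive_score(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        assert youden_threshold(scores, [1, 1, 0, 0]) == 0.8

    def test_enumerated_example(self):
        # exhaustive scan: J maximal (2/3) at threshold 0.7
        scores = [0.9, 0.7, 0.6, 0.3, 0.2]
        labels = [1, 1, 0, 1, 0]
        assert youden_threshold(scores, labels) == 0.7

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateCohortError):
            youden_threshold([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_exhaustive_scan(self, seed):
        scores, labels = random_instance(np.random.default_rng(seed + 100))
        t = youden_threshold(scores, labels)
        t_oracle, j_oracle = youden_scan(scores, labels)
        assert t == t_oracle
        tp, tn, fp, fn = confusion_by_counting(scores, labels, t)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        assert j == pytest.approx(j_oracle, abs=1e-12)


class TestConfusionMetrics:
    def test_direct_formula_example(self):
        # TP=3 TN=4 FP=1 FN=2
        scores = [0.6] * 3 + [0.4] * 2 + [0.6] + [0.4] * 4
        labels = [1] * 5 + [0] * 5
        m = confusion_metrics(scores, labels, 0.5)
        assert (m.counts.tp, m.counts.tn, m.counts.fp, m.counts.fn) == (3, 4, 1, 2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)

    def test_threshold_below_all_scores_is_all_positive_rule(self):
        m = confusion_metrics([0.3, 0.5, 0.7], [1, 0, 1], threshold=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_counting_oracle(self, seed):
        rng = np.random.default_rng(seed + 200)
        scores, labels = random_instance(rng, n_max=50)
        t = float(rng.random())
        m = confusion_metrics(scores, labels, t)
        assert (m.counts.tp, m.counts.tn, m.counts.fp, m.counts.fn) == \
            confusion_by_counting(scores, labels, t)
        assert m.counts.total == len(scores)


class TestHoldoutSplit:
    def test_study_sized_split_gives_795_training_records(self, study_cohort):
        train, test = holdout_split(study_cohort, 0.8, seed=0)
        assert len(train) == 795 and len(test) == 198

    def test_same_seed_reproduces_partition(self, study_cohort):
        a = holdout_split(study_cohort, 0.8, seed=3)
        b = holdout_split(study_cohort, 0.8, seed=3)
        assert a == b

    def test_partition_property(self, study_cohort):
        train, test = holdout_split(study_cohort, 0.8, seed=5)
        ids = {r.patient_id for r in train} | {r.patient_id for r in test}
        assert len(ids) == len(study_cohort)
        assert not ({r.patient_id for r in train} & {r.patient_id for r in test})

    def test_fraction_bounds(self, study_cohort):
        with pytest.raises(ValueError):
            holdout_split(study_cohort, 1.0, seed=0)


class TestRepeatedCV:
    def test_identical_seed_identical_summary(self, study_cohort):
        scheme = build_scheme("A")
        a = repeated_cv(study_cohort, scheme, n_rounds=2, n_folds=5, base_seed=4)
        b = repeated_cv(study_cohort, scheme, n_rounds=2, n_folds=5, base_seed=4)
        assert a == b

    def test_single_round_summary_is_degenerate(self, study_cohort):
        cv = repeated_cv(study_cohort, build_scheme("A"), n_rounds=1, n_folds=5,
                         base_seed=0)
        for metric in (cv.auc, cv.accuracy, cv.sensitivity, cv.specificity):
            assert metric.q1 == metric.median == metric.q3

    def test_quartile_ordering(self, study_cohort):
        cv = repeated_cv(study_cohort, build_scheme("A"), n_rounds=5, n_folds=5,
                         base_seed=1)
        for metric in (cv.auc, cv.accuracy, cv.sensitivity, cv.specificity):
            assert metric.q1 <= metric.median <= metric.q3

    def test_too_many_folds_for_minority_class(self):
        cohort = [make_record(patient_id=f"p{i}", node_status=1 if i < 3 else 0)
                  for i in range(40)]
        with pytest.raises(DegenerateCohortError, match="fewer folds"):
            repeated_cv(cohort, build_scheme("A"), n_rounds=1, n_folds=5, base_seed=0)

    def test_informative_model_beats_chance_under_fixed_seed(self):
        cfg = default_config(n=2_000, seed=13)
        cohort = generate_cohort(cfg)
        cv = repeated_cv(cohort, build_scheme("A"), n_rounds=2, n_folds=10, base_seed=2)
        assert cv.auc.median > 0.60


class TestStratifiedPerformance:
    def make_scored_cohort(self, seed, n=120):
        cfg = default_config(n=n, seed=seed)
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(seed)
        # scores correlated with the label so subgroup tables are non-trivial
        scores = np.clip(
            np.array([r.node_status for r in cohort]) * 0.4 + rng.random(n) * 0.5, 0, 1
        )
        return cohort, scores

    def test_overall_row_matches_confusion_metrics(self):
        cohort, scores = self.make_scored_cohort(31)
        labels = [r.node_status for r in cohort]
        df = stratified_performance(cohort, scores, threshold=0.45)
        m = confusion_metrics(scores, labels, 0.45)
        row = df[df.stratum == "overall"].iloc[0]
        assert row.sensitivity == pytest.approx(m.sensitivity)
        assert row.specificity == pytest.approx(m.specificity)
        assert row.n == len(cohort)

    def test_all_correct_stratum_reports_perfect_metrics(self):
        cohort = [make_record(patient_id="a", node_status=1),
                  make_record(patient_id="b", node_status=0)]
        df = stratified_performance(cohort, [0.9, 0.1], threshold=0.5)
        row = df[df.stratum == "overall"].iloc[0]
        assert row.sensitivity == 1.0 and row.specificity == 1.0

    def test_empty_stratum_reports_na(self):
        cohort = [make_record(patient_id="a", diameter=10.0, node_status=1),
                  make_record(patient_id="b", diameter=12.0, node_status=0)]
        df = stratified_performance(cohort, [0.9, 0.1], threshold=0.5)
        t2 = df[df.stratum == "T2"].iloc[0]
        assert t2.n == 0 and np.isnan(t2.sensitivity) and np.isnan(t2.specificity)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_agrees_with_per_stratum_counting(self, seed):
        from slncalc.evaluation import default_strata

        cohort, scores = self.make_scored_cohort(seed)
        df = stratified_performance(cohort, scores, threshold=0.45)
        for name, predicate in default_strata():
            members = [(s, r.node_status) for s, r in zip(scores, cohort) if predicate(r)]
            tp, tn, fp, fn = confusion_by_counting(
                [s for s, _ in members], [y for _, y in members], 0.45
            )
            row = df[df.stratum == name].iloc[0]
            if tp + fn:
                assert row.sensitivity == pytest.approx(tp / (tp + fn))
            else:
                assert np.isnan(row.sensitivity)
            if tn + fp:
                assert row.specificity == pytest.approx(tn / (tn + fp))
            else:
                assert np.isnan(row.specificity)
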