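"""Cross-validation splits, accuracy metrics, Fisher/DeLong tests,
matched subsets, and confound-indifference tests."""

import numpy as np
import pytest
from scipy import stats

from joigam import (
    CohortTable,
    auc,
    build_matched_subset,
    confusion_metrics,
    delong_test,
    fisher_exact_two_tailed,
    matching_diagnostics,
    two_fold_split,
)
from joigam.errors import CohortValidationError
from joigam.evaluation import _indifference_test, accuracy_significance


def simple_table(n_cases, n_controls, seed=0, **extra):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    return CohortTable(
        subject_ids=np.array([f"S{i:04d}" for i in range(n)], dtype=object),
        labels=np.array([1] * n_cases + [-1] * n_controls),
        age=rng.uniform(12, 21, n),
        metrics=rng.normal(size=(n, 2)),
        metric_names=["a", "b"],
        modality_tags=["STR", "DTI"],
        **extra,
    )


class TestTwoFoldSplit:
    def test_stratified_halving(self):
        table = simple_table(4, 8)
        f1, f2 = two_fold_split(table, seed=0)
        assert int(f1.cases_mask.sum()) == 2 and int(f2.cases_mask.sum()) == 2
        assert int(f1.controls_mask.sum()) == 4 and int(f2.controls_mask.sum()) == 4

    def test_deterministic_given_seed(self):
        table = simple_table(6, 20)
        a1 = two_fold_split(table, seed=3)
        a2 = two_fold_split(table, seed=3)
        np.testing.assert_array_equal(a1[0].subject_ids, a2[0].subject_ids)

    def test_folds_partition_the_table(self):
        table = simple_table(5, 21)
        f1, f2 = two_fold_split(table, seed=1)
        ids = sorted(list(f1.subject_ids) + list(f2.subject_ids))
        assert ids == sorted(table.subject_ids)

    def test_balances_sex_within_ten_points(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            sex = rng.choice(["M", "F"], size=60)
            table = simple_table(12, 48, seed=seed, categoricals={"sex": sex})
            f1, f2 = two_fold_split(table, seed=seed, balance_vars=["sex"])
            for f in (f1, f2):
                frac = np.mean(f.categoricals["sex"] == "M")
                assert abs(frac - np.mean(sex == "M")) < 0.10

    def test_too_few_cases_rejected(self):
        table = simple_table(1, 10)
        with pytest.raises(CohortValidationError):
            two_fold_split(table, seed=0)


class TestConfusionMetrics:
    def test_printed_sensitivity_specificity_identity(self):
        # 34 cases / 671 controls with counts chosen to print 67.6 / 84.2
        pred = np.concatenate([
            np.repeat(1, 23), np.repeat(-1, 11),      # cases: 23 TP, 11 FN
            np.repeat(-1, 565), np.repeat(1, 106),    # controls: 565 TN, 106 FP
        ])
        true = np.array([1] * 34 + [-1] * 671)
        sens, spec, nacc = confusion_metrics(pred, true)
        assert round(sens, 1) == 67.6
        assert round(spec, 1) == 84.2
        assert round(nacc, 1) == 75.9

    def test_perfect_predictions(self):
        true = np.array([1, 1, -1, -1])
        assert confusion_metrics(true, true) == (100.0, 100.0, 100.0)

    def test_degenerate_all_control_predictor(self):
        true = np.array([1] * 34 + [-1] * 671)
        pred = np.full(705, -1)
        assert confusion_metrics(pred, true) == (0.0, 100.0, 50.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([1, -1]), np.array([1, 1]))

    def test_label_permuted_predictor_concentrates_at_chance(self):
        rng = np.random.default_rng(5)
        true = np.array([1] * 30 + [-1] * 170)
        pred = np.where(rng.random(200) < 0.4, 1, -1)
        naccs = []
        for _ in range(200):
            naccs.append(confusion_metrics(rng.permutation(pred), true)[2])
        assert abs(np.mean(naccs) - 50.0) < 3.0


class TestAuc:
    def test_separated_scores_give_one(self):
        assert auc(np.array([3, 4, 1, 2.0]), np.array([1, 1, -1, -1])) == 1.0

    def test_constant_scores_give_half(self):
        assert auc(np.ones(6), np.array([1, 1, -1, -1, -1, -1])) == 0.5

    def test_pairwise_enumeration_cases(self):
        assert auc(np.array([3.0, 1.0, 2.0]), np.array([1, -1, 1])) == 1.0
        assert auc(np.array([1.0, 2.0, 3.0]), np.array([1, -1, 1])) == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.choice([-1, 1], 40)
        labels[:2] = [1, -1]
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a)
        assert auc(2 * scores + 7, labels) == pytest.approx(a)


class TestFisherExact:
    def test_enumerated_two_by_two(self):
        assert fisher_exact_two_tailed([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
        assert fisher_exact_two_tailed([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_identical_rows_give_one(self):
        assert fisher_exact_two_tailed([[3, 3], [3, 3]]) == 1.0

    def test_empty_margin_gives_one(self):
        assert fisher_exact_two_tailed([[0, 0], [3, 2]]) == 1.0

    def test_agrees_with_enumeration_for_small_tables(self):
        # brute-force all margin-preserving tables
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or np.any(t.sum(0) == 0) or np.any(t.sum(1) == 0):
                continue
            r1, r2 = t.sum(axis=1)
            c1, _ = t.sum(axis=0)
            probs = []
            for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs.append((a, stats.hypergeom.pmf(a, r1 + r2, r1, c1)))
            obs = dict(probs)[t[0, 0]]
            expected = sum(p for _, p in probs if p <= obs * (1 + 1e-9))
            assert fisher_exact_two_tailed(t) == pytest.approx(expected, rel=1e-6)


class TestDeLong:
    def test_identical_scores_give_one(self):
        scores = np.array([0.2, 0.8, 0.4, 0.9])
        labels = np.array([-1, 1, -1, 1])
        assert delong_test(scores, scores, labels) == 1.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        labels = np.array([1] * 10 + [-1] * 30)
        a = rng.normal(size=40) + (labels == 1)
        b = rng.normal(size=40)
        assert delong_test(a, b, labels) == pytest.approx(delong_test(b, a, labels))

    def test_power_against_known_auc_gap(self):
        # informative vs pure-noise scorer, true AUC gap ~ 0.25
        hits = 0
        rng = np.random.default_rng(2)
        for _ in range(100):
            labels = np.array([1] * 20 + [-1] * 20)
            good = rng.normal(size=40) + 1.35 * (labels == 1)
            noise = rng.normal(size=40)
            if delong_test(good, noise, labels) < 0.05:
                hits += 1
        assert hits >= 80

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(3)
        false_pos = 0
        for _ in range(200):
            labels = np.array([1] * 15 + [-1] * 25)
            base = rng.normal(size=40) + 0.8 * (labels == 1)
            a = base + rng.normal(0, 0.3, 40)
            b = base + rng.normal(0, 0.3, 40)
            if delong_test(a, b, labels) < 0.05:
                false_pos += 1
        assert false_pos <= 25


class TestMatchedSubset:
    def _matched_table(self):
        return simple_table(
            3, 9, seed=4,
            ses=np.random.default_rng(4).uniform(10, 20, 12),
            categoricals={
                "sex": np.array(["M", "F", "M"] * 4, dtype=object),
                "scanner": np.array(["GE"] * 12, dtype=object),
            },
        )

    def test_equal_cohort_sizes_and_no_reuse(self):
        table = self._matched_table()
        sub = build_matched_subset(table, seed=0)
        assert int(sub.cases_mask.sum()) == int(sub.controls_mask.sum()) == 3
        assert len(set(sub.subject_ids)) == sub.n

    def test_nearest_age_control_chosen(self):
        table = CohortTable(
            subject_ids=np.array(["case", "c12", "c19", "c15"], dtype=object),
            labels=np.array([1, -1, -1, -1]),
            age=np.array([19.0, 12.0, 19.1, 15.0]),
            metrics=np.zeros((4, 1)),
            metric_names=["m"],
            modality_tags=["STR"],
        )
        sub = build_matched_subset(table, seed=0)
        assert set(sub.subject_ids) == {"case", "c19"}

    def test_already_matched_table_is_permutation(self):
        table = simple_table(4, 4, seed=6)
        sub = build_matched_subset(table, seed=0)
        assert sorted(sub.subject_ids) == sorted(table.subject_ids)

    def test_fewer_controls_than_cases_rejected(self):
        table = simple_table(5, 4, seed=7)
        with pytest.raises(CohortValidationError):
            build_matched_subset(table, seed=0)


class TestIndifferenceTests:
    def test_random_predictions_pass_mostly(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(12, 21, 120)
        passes = 0
        for _ in range(100):
            pred = rng.choice([-1, 1], 120, p=[0.8, 0.2])
            _, ok = _indifference_test(pred, ages)
            passes += ok
        assert passes >= 95

    def test_age_aligned_predictions_fail(self):
        ages = np.concatenate([np.full(30, 13.0), np.full(30, 20.0)])
        pred = np.where(ages > 15, 1, -1)
        p, ok = _indifference_test(pred, ages)
        assert p < 1e-6 and not ok

    def test_constant_predictions_pass_trivially(self):
        p, ok = _indifference_test(np.full(50, -1), np.linspace(12, 21, 50))
        assert p == 1.0 and ok

    def test_accuracy_significance_chance_predictor(self):
        true = np.array([1] * 10 + [-1] * 50)
        pred = np.full(60, -1)
        assert accuracy_significance(pred, true) == 1.0


class TestMatchingDiagnostics:
    def test_reproduces_printed_cohort_comparability(self):
        # printed demographic tables: 333/338 vs 16/18 male/female,
        # 447/224 vs 25/9 GE/Siemens
        sex = np.array(
            ["M"] * 16 + ["F"] * 18 + ["M"] * 333 + ["F"] * 338, dtype=object
        )
        scanner = np.array(
            ["GE"] * 25 + ["S"] * 9 + ["GE"] * 447 + ["S"] * 224, dtype=object
        )
        n = 705
        rng = np.random.default_rng(9)
        table = CohortTable(
            subject_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
            labels=np.array([1] * 34 + [-1] * 671),
            age=rng.uniform(12, 21, n),
            metrics=rng.normal(size=(n, 1)),
            metric_names=["m"],
            modality_tags=["STR"],
            categoricals={"sex": sex, "scanner": scanner},
        )
        p = matching_diagnostics(table)
        assert p["sex"] == pytest.approx(0.7701, abs=5e-5)
        assert p["scanner"] == pytest.approx(0.4032, abs=5e-5)

    def test_identical_cohorts_give_p_one(self):
        rng = np.random.default_rng(10)
        half_age = rng.uniform(12, 21, 20)
        half_ses = rng.uniform(10, 20, 20)
        sex = rng.choice(["M", "F"], 20)
        table = CohortTable(
            subject_ids=np.array([f"S{i}" for i in range(40)], dtype=object),
            labels=np.array([1] * 20 + [-1] * 20),
            age=np.concatenate([half_age, half_age]),
            ses=np.concatenate([half_ses, half_ses]),
            metrics=rng.normal(size=(40, 1)),
            metric_names=["m"],
            modality_tags=["STR"],
            categoricals={"sex": np.concatenate([sex, sex]).astype(object)},
        )
        p = matching_diagnostics(table)
        assert p["age"] == pytest.approx(1.0)
        assert p["ses"] == pytest.approx(1.0)
        assert p["sex"] == pytest.approx(1.0)

    def test_single_level_categorical_skipped_with_warning(self):
        table = simple_table(
            3, 5, seed=11, categoricals={"scanner": np.array(["GE"] * 8, dtype=object)}
        )
        with pytest.warns(UserWarning):
            p = matching_diagnostics(table)
        assert "scanner" not in p
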