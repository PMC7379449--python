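"""Splits, folds, cross-validation arithmetic, and Cohen's kappa."""

import numpy as np
import pandas as pd
import pytest

import petasym as pa
from petasym.errors import PetasymError

LABELS_49 = ["Left"] * 27 + ["Right"] * 22


class TestHoldoutSplit:
    def test_60_40_split_of_49(self):
        plan = pa.make_split(LABELS_49, 31 / 49, seed=0)
        assert len(plan.train_idx) == 31
        assert len(plan.test_idx) == 18

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction(self, frac):
        with pytest.raises(PetasymError):
            pa.make_split(LABELS_49, frac)

    def test_reproducible(self):
        a = pa.make_split(LABELS_49, 0.63, seed=4)
        b = pa.make_split(LABELS_49, 0.63, seed=4)
        assert a.assignment.equals(b.assignment)


class TestFolds:
    def test_49_into_5_gives_10s_and_one_9(self):
        plan = pa.make_folds(LABELS_49, 5, seed=0)
        assert sorted(len(f) for f in plan.folds) == [9, 10, 10, 10, 10]

    def test_stratification_keeps_class_ratio(self):
        labels = pd.Series(LABELS_49)
        plan = pa.make_folds(labels, 5, seed=3)
        for fold in plan.folds:
            n_left = (labels.iloc[fold] == "Left").sum()
            assert 4 <= n_left <= 6  # 27/49 of 9-10 subjects, +-1

    def test_leave_one_out(self):
        plan = pa.make_folds(["Left"] * 5 + ["Right"] * 5, 10, seed=1)
        assert [len(f) for f in plan.folds] == [1] * 10

    def test_partition_property(self):
        for seed in range(5):
            plan = pa.make_folds(LABELS_49, 5, seed=seed)
            flat = np.sort(np.concatenate(plan.folds))
            assert np.array_equal(flat, np.arange(49))

    def test_k_bounds(self):
        with pytest.raises(PetasymError):
            pa.make_folds(LABELS_49, 1)
        with pytest.raises(PetasymError):
            pa.make_folds(["Left", "Right"], 3)


class TestCorrectRatio:
    def test_printed_test_set_columns(self):
        t = pa.test_set_lateralizations()
        assert tuple(pa.correct_ratio(t["j48"], t["definitive"]))[:2] == (16, 18)
        assert tuple(pa.correct_ratio(t["lmt"], t["definitive"]))[:2] == (17, 18)
        assert str(pa.correct_ratio(t["j48"], t["definitive"])) == "16/18, 89%"
        assert str(pa.correct_ratio(t["lmt"], t["definitive"])) == "17/18, 94%"

    def test_no_lateralization_counts_as_incorrect(self):
        t = pa.test_set_lateralizations()
        r = pa.correct_ratio(t["spm"], t["definitive"])
        assert (r.correct, r.total) == (16, 18)

    def test_identical_vectors(self):
        r = pa.correct_ratio(["Left", "Right"], ["Left", "Right"])
        assert r.ratio == 1.0

    def test_length_mismatch(self):
        with pytest.raises(PetasymError):
            pa.correct_ratio(["Left"], ["Left", "Right"])


class TestCohensKappa:
    def test_printed_j48_kappa_and_z(self):
        t = pa.test_set_lateralizations()
        k = pa.cohens_kappa(t["j48"], t["definitive"])
        assert round(k.kappa, 3) == 0.775
        assert round(k.z, 3) == 3.288
        assert round(k.p_value, 3) == 0.001

    def test_printed_lmt_kappa_and_z(self):
        t = pa.test_set_lateralizations()
        k = pa.cohens_kappa(t["lmt"], t["definitive"])
        assert round(k.kappa, 3) == 0.889
        assert round(k.z, 3) == 3.795
        assert k.p_value < 0.001

    def test_symmetry(self):
        t = pa.test_set_lateralizations()
        a = pa.cohens_kappa(t["j48"], t["definitive"])
        b = pa.cohens_kappa(t["definitive"], t["j48"])
        assert a.kappa == pytest.approx(b.kappa)
        assert a.z == pytest.approx(b.z)

    def test_perfect_agreement(self):
        labels = ["Left"] * 6 + ["Right"] * 4
        k = pa.cohens_kappa(labels, labels)
        assert k.kappa == pytest.approx(1.0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(PetasymError):
            pa.cohens_kappa(["Left"] * 5, ["Left"] * 5)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa
        for _ in range(5):
            a = rng.choice(["Left", "Right"], size=40)
            b = np.where(rng.random(40) < 0.7, a, rng.choice(["Left", "Right"], size=40))
            ours = pa.cohens_kappa(a, b)
            table = pd.crosstab(pd.Series(a), pd.Series(b)).reindex(
                index=["Left", "Right"], columns=["Left", "Right"], fill_value=0)
            theirs = sm_kappa(table.to_numpy(), return_results=True)
            assert ours.kappa == pytest.approx(float(theirs.kappa))
            assert ours.z == pytest.approx(float(theirs.z_value))

    def test_null_mean_near_zero(self, rng):
        kappas = []
        for _ in range(200):
            a = rng.choice(["Left", "Right"], size=30)
            b = rng.choice(["Left", "Right"], size=30)
            try:
                kappas.append(pa.cohens_kappa(a, b).kappa)
            except PetasymError:
                pass
        assert abs(np.mean(kappas)) < 0.05


class TestCrossValidate:
    def test_noise_free_separable_is_perfect(self):
        table = pa.generate_feature_table(
            pa.CohortConfig(n_subjects=30, left_fraction=0.5, ai_noise_sd=0.2, seed=5))
        for algo in ("c45", "lmt"):
            res = pa.cross_validate(table, k=5, algo=algo, seed=1)
            assert res.mean_ratio == 1.0

    def test_totals_sum_to_cohort(self, cohort_table):
        res = pa.cross_validate(cohort_table, k=5, algo="c45", seed=2)
        assert sum(r.total for r in res.per_run) == len(cohort_table)
        assert res.mean_ratio == pytest.approx(
            sum(r.correct for r in res.per_run) / len(cohort_table))

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(123)
        correct = total = 0
        for seed in range(6):
            table = pa.generate_feature_table(pa.CohortConfig(seed=seed))
            table["label"] = rng.permutation(table["label"].to_numpy())
            res = pa.cross_validate(table, k=5, algo="c45", seed=seed)
            correct += sum(r.correct for r in res.per_run)
            total += sum(r.total for r in res.per_run)
        # binomial null around 0.5; 6 cohorts x 49 subjects
        p = correct / total
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / total) + 0.05

    def test_estimator_instance_accepted(self, cohort_table):
        clf = pa.C45TreeClassifier(min_leaf=3)
        res = pa.cross_validate(cohort_table, k=5, algo=clf, seed=0)
        assert all(m.min_leaf == 3 for m in res.models)
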