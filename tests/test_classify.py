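import numpy as np
import pandas as pd
import pytest

from aidp import stats
from aidp.classify import (
    C_GRID_DEFAULT,
    ENDPOINTS,
    LinearModel,
    SplitError,
    check_no_leakage,
    evaluate_split,
    make_cv_folds,
    predict,
    run_verification,
    site_holdout_split,
    stratified_split,
    tune_and_train,
)
from aidp.synthetic import CohortSpec, cohort_to_dataframe, generate_cohort

C_FAST = (0.01, 1.0, 100.0)


def study_cohort(seed=0):
    """Cohort with the study's printed class counts."""
    return cohort_to_dataframe(generate_cohort(CohortSpec(seed=seed)))


def feature_cohort(
    n_per_class=20,
    n_retro_per_class=8,
    n_features=20,
    effect=2.0,
    n_sites=6,
    seed=0,
    site_sd=0.0,
    class_sites=None,
):
    """Small feature-level synthetic cohort: class-mean shifts on disjoint
    feature blocks, optional per-site offsets, iid noise."""
    rng = np.random.default_rng(seed)
    rows = []
    X = []
    uid = 0
    class_means = {
        "PD": np.zeros(n_features),
        "MSA": np.zeros(n_features),
        "PSP": np.zeros(n_features),
    }
    third = max(1, n_features // 3)
    class_means["MSA"][:third] = effect
    class_means["PSP"][third : 2 * third] = effect
    site_offsets = {
        f"site{i:02d}": rng.normal(0, site_sd, n_features) for i in range(n_sites)
    }
    for cohort_name, n_count in (("prospective", n_per_class), ("retrospective", n_retro_per_class)):
        for dx in ("PD", "MSA", "PSP"):
            for _ in range(n_count):
                if class_sites is not None:
                    site = f"site{rng.choice(class_sites[dx]):02d}"
                else:
                    site = f"site{rng.integers(n_sites):02d}"
                rows.append(
                    dict(
                        subject_id=f"s{uid:03d}", site=site, cohort=cohort_name,
                        diagnosis=dx, age=65.0, sex="male",
                    )
                )
                X.append(class_means[dx] + site_offsets[site] + rng.normal(0, 1, n_features))
                uid += 1
    return pd.DataFrame(rows), np.array(X)


class TestEndpoints:
    def test_four_endpoints(self):
        assert set(ENDPOINTS) == {"PD_vs_AP", "MSA_vs_PSP", "PD_vs_MSA", "PD_vs_PSP"}

    def test_pd_vs_ap_excludes_nothing(self):
        spec = ENDPOINTS["PD_vs_AP"]
        assert spec.label("MSA") == 1 and spec.label("PSP") == 1
        assert spec.label("PD") == 0

    def test_pairwise_exclusions(self):
        assert ENDPOINTS["MSA_vs_PSP"].label("PD") is None
        assert ENDPOINTS["PD_vs_MSA"].label("PSP") is None
        assert ENDPOINTS["PD_vs_PSP"].label("MSA") is None

    def test_atypical_positive_convention(self):
        assert ENDPOINTS["MSA_vs_PSP"].label("PSP") == 1
        assert ENDPOINTS["PD_vs_MSA"].label("MSA") == 1
        assert ENDPOINTS["PD_vs_PSP"].label("PSP") == 1


class TestStratifiedSplit:
    def test_study_counts(self):
        cohort = study_cohort()
        plan = stratified_split(
            cohort, test_counts={"PD": 60, "MSA": 27, "PSP": 58}, seed=1
        )
        merged = cohort.set_index("subject_id")
        test_dx = merged.loc[plan.test_ids, "diagnosis"].value_counts()
        assert test_dx["PD"] == 60 and test_dx["MSA"] == 27 and test_dx["PSP"] == 58
        train = merged.loc[plan.train_ids]
        pro_train = train[train["cohort"] == "prospective"]["diagnosis"].value_counts()
        assert pro_train["PD"] == 39 and pro_train["MSA"] == 26 and pro_train["PSP"] == 39
        assert len(plan.train_ids) == 500
        assert len(plan.test_ids) == 145

    def test_retrospective_always_train(self):
        cohort = study_cohort()
        plan = stratified_split(cohort, test_fraction=0.5, seed=0)
        retro = set(cohort[cohort["cohort"] == "retrospective"]["subject_id"])
        assert retro <= set(plan.train_ids)

    def test_fraction_zero_all_train(self):
        cohort = study_cohort()
        plan = stratified_split(cohort, test_fraction=0.0, seed=0,
                                ensure_site_coverage=False)
        assert not plan.test_ids
        assert len(plan.train_ids) == len(cohort)

    def test_seed_changes_membership_not_counts(self):
        cohort = study_cohort()
        counts = {"PD": 60, "MSA": 27, "PSP": 58}
        p1 = stratified_split(cohort, test_counts=counts, seed=1)
        p2 = stratified_split(cohort, test_counts=counts, seed=2)
        assert set(p1.test_ids) != set(p2.test_ids)
        m = cohort.set_index("subject_id")
        vc1 = m.loc[p1.test_ids, "diagnosis"].value_counts()
        vc2 = m.loc[p2.test_ids, "diagnosis"].value_counts()
        assert vc1.to_dict() == vc2.to_dict()

    def test_infeasible_counts_raise(self):
        cohort = study_cohort()
        with pytest.raises(SplitError):
            stratified_split(cohort, test_counts={"PD": 1000, "MSA": 0, "PSP": 0})

    def test_all_sites_in_both_sets(self):
        cohort = study_cohort()
        plan = stratified_split(
            cohort, test_counts={"PD": 60, "MSA": 27, "PSP": 58}, seed=3
        )
        pro = cohort[cohort["cohort"] == "prospective"].set_index("subject_id")
        test_sites = set(pro.loc[[s for s in plan.test_ids], "site"])
        train_sites = set(
            pro.loc[[s for s in plan.train_ids if s in pro.index], "site"]
        )
        all_sites = set(pro["site"])
        assert test_sites == all_sites
        assert train_sites == all_sites

    def test_no_leakage(self):
        plan = stratified_split(study_cohort(), test_fraction=0.3, seed=0)
        assert check_no_leakage(plan)


class TestCvFolds:
    def test_500_training_subjects_folds_of_100(self):
        cohort = study_cohort()
        plan = stratified_split(
            cohort, test_counts={"PD": 60, "MSA": 27, "PSP": 58}, seed=1
        )
        folds = make_cv_folds(plan, cohort, k=5, seed=0)
        sizes = pd.Series(list(folds.values())).value_counts()
        assert sorted(sizes) == [100] * 5

    def test_seven_subjects_five_folds(self):
        cohort = pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(7)],
                site="site01", cohort="prospective", diagnosis="PD",
            )
        )
        plan = stratified_split(cohort, test_fraction=0.0, seed=0,
                                ensure_site_coverage=False)
        folds = make_cv_folds(plan, cohort, k=5, seed=0)
        sizes = sorted(pd.Series(list(folds.values())).value_counts())
        assert sizes == [1, 1, 1, 2, 2]

    def test_per_class_sizes_differ_by_at_most_one(self):
        cohort = study_cohort()
        plan = stratified_split(cohort, test_fraction=0.3, seed=2)
        folds = make_cv_folds(plan, cohort, k=5, seed=2)
        merged = cohort.set_index("subject_id")
        for dx in ("PD", "MSA", "PSP"):
            per_fold = pd.Series(
                {f: sum(1 for s, ff in folds.items()
                        if ff == f and merged.loc[s, "diagnosis"] == dx)
                 for f in range(1, 6)}
            )
            assert per_fold.max() - per_fold.min() <= 1

    def test_small_class_raises(self):
        cohort = pd.DataFrame(
            dict(
                subject_id=[f"s{i}" for i in range(8)],
                site="site01", cohort="prospective",
                diagnosis=["PD"] * 5 + ["MSA"] * 3,
            )
        )
        plan = stratified_split(cohort, test_fraction=0.0, seed=0,
                                ensure_site_coverage=False)
        with pytest.raises(SplitError, match="MSA"):
            make_cv_folds(plan, cohort, k=5, seed=0)


class TestTuneAndTrain:
    def separable_toy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal([1, 1], 0.1, (10, 2)),
            rng.normal([-1, -1], 0.1, (10, 2)),
        ])
        y = np.array([1] * 10 + [0] * 10)
        folds = np.tile([1, 2, 3, 4, 5], 4)
        return X, y, folds

    def test_separable_training_auroc_one(self):
        X, y, folds = self.separable_toy()
        model = tune_and_train(X, y, folds, C_FAST)
        margins = model.margins(X)
        assert stats.auroc(stats.ScoreSet.from_labels(margins, y)) == 1.0
        assert np.all(model.weights > 0)

    def test_permuted_labels_chance_cv(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 10))
        y = rng.permutation([0, 1] * 100)
        folds = np.tile([1, 2, 3, 4, 5], 40)
        model = tune_and_train(X, y, folds, C_FAST)
        assert abs(model.cv_auroc - 0.5) <= 0.1

    def test_planted_feature_gets_largest_weight(self):
        rng = np.random.default_rng(2)
        n, d = 120, 266
        X = rng.normal(size=(n, d))
        y = np.array([0, 1] * (n // 2))
        X[:, 42] += 3.0 * y
        folds = np.tile([1, 2, 3, 4, 5], n // 5)
        model = tune_and_train(X, y, folds, C_FAST)
        assert np.argmax(np.abs(model.weights)) == 42

    def test_tie_break_prefers_smallest_c(self):
        X, y, folds = self.separable_toy()
        model = tune_and_train(X, y, folds, C_FAST)
        # fully separable: every C achieves CV AUROC 1.0 -> smallest C wins
        assert model.C == min(C_FAST)

    def test_zero_variance_feature_handled(self):
        X, y, folds = self.separable_toy()
        X = np.hstack([X, np.full((X.shape[0], 1), 7.0)])
        model = tune_and_train(X, y, folds, C_FAST)
        assert np.isfinite(model.weights).all()

    def test_fold_missing_class_raises(self):
        X, y, _ = self.separable_toy()
        folds = np.array([1] * 10 + [2] * 10)  # fold 1 all positive
        with pytest.raises(SplitError):
            tune_and_train(X, y, folds, C_FAST)


class TestPredict:
    def test_margin_zero_gives_half_with_symmetric_calibration(self):
        model = LinearModel(
            weights=np.array([1.0]), bias=0.0, C=1.0,
            scale_mean=np.zeros(1), scale_sd=np.ones(1),
            calib_a=-2.0, calib_b=0.0,
        )
        assert model.predict_proba(np.array([[0.0]]))[0] == pytest.approx(0.5)

    def test_probability_monotone_in_margin(self):
        model = LinearModel(
            weights=np.array([1.0]), bias=0.0, C=1.0,
            scale_mean=np.zeros(1), scale_sd=np.ones(1),
            calib_a=-1.5, calib_b=0.3,
        )
        xs = np.linspace(-3, 3, 13)[:, None]
        probs = model.predict_proba(xs)
        assert np.all(np.diff(probs) > 0)

    def test_separable_toy_test_points_correct(self):
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.normal([1, 1], 0.1, (10, 2)), rng.normal([-1, -1], 0.1, (10, 2))
        ])
        y = np.array([1] * 10 + [0] * 10)
        folds = np.tile([1, 2, 3, 4, 5], 4)
        model = tune_and_train(X, y, folds, C_FAST)
        X_test = np.array([[1.2, 0.9], [-0.8, -1.1]])
        labels = model.predict_label(X_test)
        np.testing.assert_array_equal(labels, [1, 0])

    def test_length_mismatch_raises(self):
        model = LinearModel(
            weights=np.ones(3), bias=0.0, C=1.0,
            scale_mean=np.zeros(3), scale_sd=np.ones(3),
            calib_a=-1.0, calib_b=0.0,
        )
        with pytest.raises(ValueError):
            model.margins(np.ones((2, 4)))

    def test_probability_estimates_structure(self):
        model = LinearModel(
            weights=np.ones(2), bias=0.0, C=1.0,
            scale_mean=np.zeros(2), scale_sd=np.ones(2),
            calib_a=-1.0, calib_b=0.0, endpoint="PD_vs_AP",
        )
        est = predict(model, np.ones((3, 2)), subject_ids=["a", "b", "c"])
        assert [e.subject_id for e in est] == ["a", "b", "c"]
        assert all(0 <= e.probability <= 1 for e in est)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        model = LinearModel(
            weights=rng.normal(size=5), bias=0.3, C=10.0,
            scale_mean=rng.normal(size=5), scale_sd=rng.uniform(0.5, 2, 5),
            calib_a=-1.2, calib_b=0.1,
            feature_names=tuple("abcde"), endpoint="PD_vs_MSA", seed=7,
            cv_auroc=0.93,
        )
        model.to_json(tmp_path / "m.json")
        back = LinearModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.C == model.C and back.endpoint == model.endpoint
        x = rng.normal(size=(3, 5))
        np.testing.assert_allclose(back.predict_proba(x), model.predict_proba(x))


class TestEvaluateSplit:
    def test_strong_effect_all_endpoints_separate(self):
        cohort, X = feature_cohort(effect=4.0, seed=5)
        plan = stratified_split(cohort, test_fraction=0.4, seed=5)
        reports, estimates = evaluate_split(X, cohort, plan, C_grid=C_FAST, seed=5)
        assert len(reports) == 4
        for r in reports:
            assert r.auroc >= 0.9
            assert r.bh_adjusted_p is not None
        assert set(estimates) == set(r.endpoint for r in reports)

    def test_age_sex_removal_insensitive(self):
        # imaging-borne effects: dropping the last two (constant demographic)
        # features barely moves test AUROC
        cohort, X = feature_cohort(effect=2.0, n_features=22, seed=6)
        plan = stratified_split(cohort, test_fraction=0.4, seed=6)
        full, _ = evaluate_split(X, cohort, plan, C_grid=C_FAST, seed=6)
        plan2 = stratified_split(cohort, test_fraction=0.4, seed=6)
        reduced, _ = evaluate_split(X[:, :-2], cohort, plan2, C_grid=C_FAST, seed=6)
        for r_full, r_red in zip(full, reduced):
            assert abs(r_full.auroc - r_red.auroc) < 0.02


class TestVerificationRuns:
    def test_n_runs_reports(self):
        cohort, X = feature_cohort(effect=3.0, seed=7)
        runs = run_verification(
            X, cohort, {"PD": 8, "MSA": 8, "PSP": 8}, n_runs=3, seed=7,
            endpoints=("PD_vs_AP",), C_grid=C_FAST,
        )
        assert len(runs) == 3
        assert all(len(r) == 1 for r in runs)

    def test_first_run_matches_primary(self):
        cohort, X = feature_cohort(effect=3.0, seed=8)
        counts = {"PD": 8, "MSA": 8, "PSP": 8}
        runs = run_verification(
            X, cohort, counts, n_runs=1, seed=8, endpoints=("PD_vs_AP",),
            C_grid=C_FAST,
        )
        plan = stratified_split(cohort, test_counts=counts, seed=8)
        primary, _ = evaluate_split(
            X, cohort, plan, ("PD_vs_AP",), C_FAST, seed=8
        )
        assert runs[0][0].auroc == primary[0].auroc

    def test_strong_effect_high_aurocs(self):
        cohort, X = feature_cohort(effect=4.0, n_per_class=25, seed=9)
        runs = run_verification(
            X, cohort, {"PD": 10, "MSA": 10, "PSP": 10}, n_runs=5, seed=9,
            endpoints=("PD_vs_AP",), C_grid=C_FAST,
        )
        for run in runs:
            assert run[0].auroc >= 0.9


class TestSiteHoldout:
    def test_sites_disjoint(self):
        cohort = study_cohort()
        plan = site_holdout_split(cohort, n_holdout_sites=6, seed=0)
        pro = cohort[cohort["cohort"] == "prospective"].set_index("subject_id")
        test_sites = {pro.loc[s, "site"] for s in plan.test_ids}
        train_sites = {
            pro.loc[s, "site"] for s in plan.train_ids if s in pro.index
        }
        assert len(test_sites) == 6
        assert len(train_sites) == 15
        assert not (test_sites & train_sites)

    def test_too_few_sites_raises(self):
        cohort, _ = feature_cohort(n_sites=2)
        with pytest.raises(SplitError):
            site_holdout_split(cohort, n_holdout_sites=6)

    def test_retrospective_in_training(self):
        cohort = study_cohort()
        plan = site_holdout_split(cohort, n_holdout_sites=6, seed=1)
        retro = set(cohort[cohort["cohort"] == "retrospective"]["subject_id"])
        assert retro <= set(plan.train_ids)

    def test_site_confounded_effect_degrades_holdout(self):
        # class signal carried entirely by site offsets: a random split can
        # exploit memorized sites, a site holdout cannot
        class_sites = {"PD": [0, 1, 2, 3], "MSA": [4, 5, 6, 7], "PSP": [8, 9, 10, 11]}
        cohort, X = feature_cohort(
            n_per_class=24, n_retro_per_class=0, effect=0.0, n_sites=12,
            site_sd=3.0, class_sites=class_sites, seed=10,
        )
        plan_rs = stratified_split(cohort, test_fraction=0.3, seed=10,
                                   ensure_site_coverage=False)
        rs, _ = evaluate_split(X, cohort, plan_rs, ("PD_vs_AP",), C_FAST, seed=10)
        plan_sh = site_holdout_split(cohort, n_holdout_sites=3, seed=10)
        sh, _ = evaluate_split(X, cohort, plan_sh, ("PD_vs_AP",), C_FAST, seed=10)
        assert sh[0].auroc <= rs[0].auroc
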