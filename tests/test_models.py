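"""LASSO / random-forest regressors, leave-one-animal-out CV hygiene,
grid search and feature-importance ranking."""

import numpy as np
import pandas as pd
import pytest

from blvest.models import (
    CVResult,
    ModelSpec,
    grid_search_rf,
    loao_cv,
    make_estimator,
    rank_features,
    train,
)


def planted_frame(n_subjects=4, n_windows=40, driver_slope=10.0, seed=0):
    """Feature table whose label is linear in one feature, others noise.

    Columns mimic the wide cohort layout closely enough for loao_cv via
    a tiny modality patch: we use the ABP modality names so only 12
    feature columns are needed.
    """
    from blvest.features import ABP_FEATURES, PR_FEATURES

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for k in range(n_windows):
            phase = "baseline" if k < 8 else "bleeding"
            driver = 1.0 + 0.02 * k + rng.normal(0, 0.002)
            label = 0.0 if phase == "baseline" else driver_slope * (driver - 1.16) * 50
            row = {
                "subject_id": f"s{s}",
                "start_s": 30.0 * k,
                "phase": phase,
                "label_blv": max(label, 0.0),
                "quality_ok": True,
                "usable_ppg": False,
                "usable_abp": True,
            }
            for i, name in enumerate(ABP_FEATURES):
                row[name] = driver if i == 0 else rng.uniform(0.9, 1.1)
            for name in PR_FEATURES:
                row[f"{name} [abp]"] = rng.uniform(0.9, 1.1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestTrain:
    def test_lasso_infinite_alpha_predicts_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.normal(10.0, 2.0, 50)
        spec = ModelSpec("LASSO", "ABP", "none", {"alpha": 1e9})
        est = train(spec, X, y)
        assert np.allclose(est.coef_, 0.0)
        assert est.predict(X.iloc[:3].to_numpy())[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_lasso_finds_planted_driver(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = 40.0 * X["c"].to_numpy() + rng.normal(0, 0.5, n)
        est = train(ModelSpec("LASSO", "ABP", "none", {"alpha": 0.05}), X, y)
        assert np.argmax(np.abs(est.coef_)) == 2

    def test_rf_single_split_separates_clusters(self):
        # depth-1 trees on two well-separated clusters: each prediction is
        # an average of per-tree leaf means, so it must land inside the
        # matching cluster's label range
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        y = np.array([1.0, 2.0, 3.0, 101.0, 102.0, 103.0])
        spec = ModelSpec("RF", "ABP", "none", {"n_estimators": 50, "max_depth": 1}, seed=1)
        est = train(spec, X, y)
        pred_lo = est.predict([[1.0]])[0]
        pred_hi = est.predict([[11.0]])[0]
        assert 1.0 <= pred_lo <= 10.0
        assert 95.0 <= pred_hi <= 103.0
        assert pred_hi - pred_lo > 80.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(ModelSpec("RF", "ABP", "none"), pd.DataFrame(), [])

    def test_nonfinite_features_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError):
            train(ModelSpec("LASSO", "ABP", "none"), X, [0.0, 1.0])

    def test_default_hyperparameters_per_modality(self):
        assert ModelSpec("RF", "PPG").resolved_hyperparameters() == {"n_estimators": 34, "max_depth": 12}
        assert ModelSpec("RF", "ABP").resolved_hyperparameters() == {"n_estimators": 15, "max_depth": 8}
        assert ModelSpec("RF", "PPG&ABP").resolved_hyperparameters() == {"n_estimators": 43, "max_depth": 19}
        assert ModelSpec("LASSO", "PPG").resolved_hyperparameters()["alpha"] == 0.05


class TestLoaoCV:
    def test_every_subject_held_out_once(self):
        df = planted_frame(n_subjects=3)
        cv = loao_cv(ModelSpec("LASSO", "ABP", "none"), df)
        held = cv.predictions["subject_id"].unique()
        assert sorted(held) == ["s0", "s1", "s2"]
        assert set(cv.fold_importances.index) == {"s0", "s1", "s2"}
        # each subject's windows predicted exactly once
        counts = cv.predictions.groupby("subject_id").size()
        assert (counts == 40).all()

    def test_training_folds_exclude_held_out_subject(self):
        # leakage sentinel: corrupt one subject's feature rows and labels;
        # that subject's fold trains on the others, so its training-matrix
        # hash must not change
        df = planted_frame(n_subjects=3)
        spec = ModelSpec("RF", "ABP", "none", {"n_estimators": 5, "max_depth": 3}, seed=2)
        before = loao_cv(spec, df, collect_hashes=True).fold_train_hashes
        poisoned = df.copy()
        rows = poisoned["subject_id"] == "s1"
        from blvest.features import ABP_FEATURES

        poisoned.loc[rows, ABP_FEATURES] = 123.0
        poisoned.loc[rows, "label_blv"] = 9999.0
        after = loao_cv(spec, poisoned, collect_hashes=True).fold_train_hashes
        assert before["s1"] == after["s1"]
        assert before["s0"] != after["s0"]  # others do see s1's rows

    def test_group_normalization_centers_exclude_test_subject(self):
        # poisoning the held-out subject's baseline cannot move its fold's
        # group center, so its training matrix hash is stable
        df = planted_frame(n_subjects=3)
        spec = ModelSpec("LASSO", "ABP", "group", seed=2)
        before = loao_cv(spec, df, collect_hashes=True).fold_train_hashes
        poisoned = df.copy()
        rows = (poisoned["subject_id"] == "s1") & (poisoned["phase"] == "baseline")
        from blvest.features import ABP_FEATURES

        poisoned.loc[rows, ABP_FEATURES] = 777.0
        after = loao_cv(spec, poisoned, collect_hashes=True).fold_train_hashes
        assert before["s1"] == after["s1"]

    def test_seeded_determinism(self):
        df = planted_frame(n_subjects=3)
        spec = ModelSpec("RF", "ABP", "person", {"n_estimators": 10, "max_depth": 4}, seed=7)
        a = loao_cv(spec, df)
        b = loao_cv(spec, df)
        assert a.predictions.equals(b.predictions)
        assert a.fold_importances.equals(b.fold_importances)

    def test_out_of_fold_predictions_track_labels(self, fast_features):
        spec = ModelSpec("RF", "PPG&ABP", "person", seed=3)
        cv = loao_cv(spec, fast_features)
        r = np.corrcoef(cv.predictions["predicted_blv"], cv.predictions["label_blv"])[0, 1]
        assert r >= 0.9

    def test_clip_zero_option(self):
        df = planted_frame(n_subjects=3)
        spec = ModelSpec("LASSO", "ABP", "none", {"alpha": 0.01}, seed=1, clip_zero=True)
        cv = loao_cv(spec, df)
        assert (cv.predictions["predicted_blv"] >= 0).all()

    def test_needs_two_subjects(self):
        df = planted_frame(n_subjects=1)
        with pytest.raises(ValueError):
            loao_cv(ModelSpec("LASSO", "ABP", "none"), df)


class TestRanking:
    def test_planted_driver_ranked_first(self):
        from blvest.features import ABP_FEATURES

        df = planted_frame(n_subjects=4)
        for method in ("LASSO", "RF"):
            hp = {} if method == "LASSO" else {"n_estimators": 20, "max_depth": 5}
            cv = loao_cv(ModelSpec(method, "ABP", "none", hp, seed=4), df)
            ranks = rank_features(cv)
            assert ranks.iloc[0]["feature"] == ABP_FEATURES[0]
            assert ranks.iloc[0]["rank"] == 1

    def test_ranks_are_permutation(self):
        df = planted_frame(n_subjects=3)
        cv = loao_cv(ModelSpec("LASSO", "ABP", "none"), df)
        ranks = rank_features(cv)
        assert sorted(ranks["rank"]) == list(range(1, 13))
        assert len(set(ranks["feature"])) == 12

    def test_zero_coefficient_count_matches_enumeration(self):
        df = planted_frame(n_subjects=3)
        cv = loao_cv(ModelSpec("LASSO", "ABP", "none", {"alpha": 5.0}), df)
        assert cv.fold_zero_counts is not None
        # enumeration oracle per fold, recomputed from refit models
        from blvest.features import design_matrix
        from blvest.normalize import normalize_person  # noqa: F401  (person not used here)

        X, meta = design_matrix(df, "ABP")
        for sid, reported in cv.fold_zero_counts.items():
            tr = meta["subject_id"] != sid
            est = train(
                ModelSpec("LASSO", "ABP", "none", {"alpha": 5.0}),
                X[tr], meta.loc[tr, "label_blv"],
                seed=None,
            )
            assert reported == int(np.sum(est.coef_ == 0.0))

    def test_zero_count_nondecreasing_in_alpha(self):
        df = planted_frame(n_subjects=3)
        counts = []
        for alpha in (0.01, 0.5, 5.0, 50.0):
            cv = loao_cv(ModelSpec("LASSO", "ABP", "none", {"alpha": alpha}), df)
            counts.append(cv.fold_zero_counts.mean())
        assert all(b >= a for a, b in zip(counts[:-1], counts[1:]))


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)))
        y = rng.normal(size=60)
        g = np.repeat(["a", "b", "c"], 20)
        best = grid_search_rf(X, y, g, [7], [3], seed=0)
        assert (best["n_estimators"], best["max_depth"]) == (7, 3)

    def test_order_independent(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)))
        y = X.iloc[:, 0].to_numpy() * 5 + rng.normal(0, 0.1, 60)
        g = np.repeat(["a", "b", "c"], 20)
        b1 = grid_search_rf(X, y, g, [5, 20], [2, 6], seed=1)
        b2 = grid_search_rf(X, y, g, [20, 5], [6, 2], seed=1)
        assert b1 == b2

    def test_recovers_planted_complexity(self, rng):
        # step-function response needs depth >= 2; deep grid point should
        # beat depth 1 on held-out subjects
        n = 120
        X = pd.DataFrame({"x": rng.uniform(0, 4, n)})
        y = np.floor(X["x"]).to_numpy() * 10.0 + rng.normal(0, 0.1, n)
        g = np.repeat(["a", "b", "c"], 40)
        best = grid_search_rf(X, y, g, [30], [1, 2, 3], seed=2)
        assert best["max_depth"] >= 2

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_rf(pd.DataFrame({"x": [1.0, 2.0]}), [0, 1], ["a", "b"], [], [3])
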