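"""Feature assembly, standardization, selection, and the four model kinds."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVR

from iolstack import (
    FeatureSet,
    MissingConstantError,
    StandardizationStats,
    assemble_features,
    fit_nn_ensemble,
    fit_regressor,
    predict_cohort,
    predict_stacker,
    select_base_formula,
    select_feature_subset,
    train_stacker,
)

STANDARD_FEATURES = (
    "axial_length", "corneal_radius", "acd", "lens_thickness",
    "iol_power", "formula_prediction",
)


class TestStandardizer:
    def test_population_sd_convention(self):
        stats = StandardizationStats.fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        z = stats.apply(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))["x"].to_numpy()
        assert z == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_training_columns_standardized_to_machine_precision(self, small_split, small_constants):
        train, _ = small_split
        X, _ = assemble_features(train, {m: small_constants["*"] for m in
                                         ("LENS-A", "LENS-B", "LENS-C")},
                                 FeatureSet(STANDARD_FEATURES))
        stats = StandardizationStats.fit(X)
        Z = stats.apply(X)
        assert np.abs(Z.mean()).max() < 1e-9
        assert np.abs(Z.std(ddof=0) - 1).max() < 1e-9

    def test_round_trip_inversion(self):
        X = pd.DataFrame({"a": [1.0, 4.0, 6.0], "b": [0.1, 0.3, -0.2]})
        stats = StandardizationStats.fit(X)
        assert np.allclose(stats.invert(stats.apply(X)), X)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            StandardizationStats.fit(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


class TestAssembleFeatures:
    def test_formula_column_matches_direct_prediction(self, small_split, small_constants):
        train, _ = small_split
        frame = train.to_frame().head(3)
        consts = {m: small_constants["*"] for m in frame["iol_model"].unique()}
        X, y = assemble_features(frame, consts,
                                 FeatureSet(("axial_length", "formula_prediction")))
        assert X.shape == (3, 2)
        assert np.allclose(X["formula_prediction"], predict_cohort("srkt", frame, consts))
        assert y == pytest.approx(frame["postop_se"].to_numpy())

    def test_standard_feature_combination_assembles_six_columns(self, small_split, small_constants):
        train, _ = small_split
        consts = {m: small_constants["*"] for m in ("LENS-A", "LENS-B", "LENS-C")}
        X, _ = assemble_features(train, consts, FeatureSet(STANDARD_FEATURES))
        assert list(X.columns) == list(STANDARD_FEATURES)

    def test_iol_constant_varies_by_lens_model(self, small_split):
        train, _ = small_split
        frame = train.to_frame()
        consts = {"LENS-A": {"A": 119.0}, "LENS-B": {"A": 119.5}, "LENS-C": {"A": 118.6}}
        X, _ = assemble_features(frame, consts, FeatureSet(("iol_constant",)))
        got = {m: set(X.loc[frame["iol_model"] == m, "iol_constant"]) for m in consts}
        assert got == {m: {c["A"]} for m, c in consts.items()}

    def test_missing_constant_names_lens(self, small_split):
        train, _ = small_split
        with pytest.raises(MissingConstantError, match="LENS"):
            assemble_features(train, {"LENS-A": {"A": 119.0}}, FeatureSet(STANDARD_FEATURES))

    def test_missing_target_rejected_in_training_mode(self, small_split, small_constants):
        train, _ = small_split
        frame = train.to_frame().copy()
        frame.loc[frame.index[0], "postop_se"] = np.nan
        consts = {m: small_constants["*"] for m in frame["iol_model"].unique()}
        with pytest.raises(ValueError, match="postop_se"):
            assemble_features(frame, consts, FeatureSet(("axial_length",)))


class TestSelection:
    def test_base_formula_tracks_the_informative_prediction(self, small_split, small_constants):
        # craft a target that is a noisy monotone function of the SRK/T
        # prediction alone: the selector must pick srkt
        train, _ = small_split
        frame = train.to_frame().copy()
        consts = {m: small_constants["*"] for m in frame["iol_model"].unique()}
        rng = np.random.default_rng(0)
        srkt = predict_cohort("srkt", frame, consts)
        frame["postop_se"] = 0.8 * srkt + 0.02 * rng.standard_normal(len(frame))
        best, importances = select_base_formula(frame, consts, seed=0)
        assert best == "srkt"
        assert importances["pred_srkt"] == max(importances[f"pred_{f}"]
                                               for f in ("srkt", "holladay1", "hofferq", "haigis"))

    def test_subset_search_finds_the_informative_feature(self, small_split, small_constants):
        train, _ = small_split
        frame = train.to_frame().copy()
        consts = {m: small_constants["*"] for m in frame["iol_model"].unique()}
        rng = np.random.default_rng(1)
        frame["postop_se"] = (
            -0.4 * (frame["axial_length"] - 24.0) + 0.05 * rng.standard_normal(len(frame))
        )
        report = select_feature_subset(
            frame, consts, "srkt",
            candidates=("axial_length", "wtw", "age"), cv_folds=5, seed=0,
        )
        assert "axial_length" in report.selected
        assert all(v >= 0 for v in report.importances.values())
        assert len(report.subset_scores) == 2 ** 3 - 1
        # pure-noise features must not beat the informative one
        assert report.subset_scores[("axial_length",)] <= report.subset_scores[("wtw", "age")]

    def test_subset_search_deterministic(self, small_split, small_constants):
        train, _ = small_split
        frame = train.to_frame()
        consts = {m: small_constants["*"] for m in frame["iol_model"].unique()}
        kw = dict(candidates=("axial_length", "acd"), cv_folds=5, seed=0)
        a = select_feature_subset(frame, consts, "srkt", **kw)
        b = select_feature_subset(frame, consts, "srkt", **kw)
        assert a.selected == b.selected and a.subset_scores == b.subset_scores


@pytest.fixture(scope="module")
def standardized_training(small_split_mod, small_constants_mod):
    train, test = small_split_mod
    consts = {m: small_constants_mod["*"] for m in ("LENS-A", "LENS-B", "LENS-C")}
    fs = FeatureSet(STANDARD_FEATURES)
    X, y = assemble_features(train, consts, fs)
    stats = StandardizationStats.fit(X)
    return stats.apply(X), y


# module-scoped clones of the session fixtures (pytest cannot mix scopes here)
@pytest.fixture(scope="module")
def small_split_mod(request):
    return request.getfixturevalue("small_split")


@pytest.fixture(scope="module")
def small_constants_mod(request):
    return request.getfixturevalue("small_constants")


class TestRegressors:
    def test_grid_of_size_one_equals_direct_fit(self, standardized_training):
        Z, y = standardized_training
        est, params, _ = fit_regressor("svr", Z, y, grid={"C": [1.0]}, seed=0)
        direct = SVR(kernel="rbf", C=1.0).fit(Z.to_numpy(), y)
        assert np.allclose(est.predict(Z.to_numpy()), direct.predict(Z.to_numpy()))
        assert params == {"C": 1.0}

    def test_empty_grid_rejected(self, standardized_training):
        Z, y = standardized_training
        with pytest.raises(ValueError, match="grid"):
            fit_regressor("gbr", Z, y, grid={}, seed=0)

    @pytest.mark.parametrize("kind", ["svr", "gbr"])
    def test_row_order_invariance(self, standardized_training, kind):
        Z, y = standardized_training
        grid = {"C": [1.0]} if kind == "svr" else {"n_estimators": [50]}
        perm = np.random.default_rng(0).permutation(len(Z))
        a, _, _ = fit_regressor(kind, Z, y, grid=grid, cv_folds=3, seed=0)
        b, _, _ = fit_regressor(kind, Z.iloc[perm], y[perm], grid=grid, cv_folds=3, seed=0)
        assert np.allclose(a.predict(Z.to_numpy()), b.predict(Z.to_numpy()), atol=1e-9)

    def test_refit_deterministic(self, standardized_training):
        Z, y = standardized_training
        grid = {"learning_rate": [0.1], "n_estimators": [50]}
        a, _, _ = fit_regressor("gbr", Z, y, grid=grid, seed=0)
        b, _, _ = fit_regressor("gbr", Z, y, grid=grid, seed=0)
        assert np.array_equal(a.predict(Z.to_numpy()), b.predict(Z.to_numpy()))


class TestNnEnsemble:
    def test_single_repeat_equals_member(self, standardized_training):
        Z, y = standardized_training
        members, _ = fit_nn_ensemble(Z, y, n_repeats=1, seeds=[0])
        mean = np.stack([m.predict(Z.to_numpy()) for m in members]).mean(axis=0)
        assert np.array_equal(mean, members[0].predict(Z.to_numpy()))

    def test_ensemble_mean_is_exact_member_average(self, standardized_training):
        Z, y = standardized_training
        members, _ = fit_nn_ensemble(Z, y, n_repeats=4, seeds=range(4))
        preds = np.stack([m.predict(Z.to_numpy()) for m in members])
        from iolstack import TrainedStacker
        stacker = TrainedStacker("nn", members, {}, None, None)
        assert np.allclose(stacker.predict_standardized(Z), preds.mean(axis=0))

    def test_averaging_shrinks_seed_variance(self, standardized_training):
        # disjoint 4-member averages fluctuate less across seeds than
        # single members do (the reason the ensemble is averaged)
        Z, y = standardized_training
        members, _ = fit_nn_ensemble(Z, y, n_repeats=12, seeds=range(12))
        preds = np.stack([m.predict(Z.to_numpy()) for m in members])
        single_sd = preds.std(axis=0).mean()
        group_means = preds.reshape(3, 4, -1).mean(axis=1)
        group_sd = group_means.std(axis=0).mean()
        assert group_sd < single_sd

    def test_fixed_seeds_reproduce_bitwise(self, standardized_training):
        Z, y = standardized_training
        a, _ = fit_nn_ensemble(Z, y, n_repeats=2, seeds=[0, 1])
        b, _ = fit_nn_ensemble(Z, y, n_repeats=2, seeds=[0, 1])
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.predict(Z.to_numpy()), mb.predict(Z.to_numpy()))


class TestTrainPredict:
    def test_overfit_sanity_single_unpruned_tree(self, small_split, small_constants):
        train, _ = small_split
        consts = {m: small_constants["*"] for m in ("LENS-A", "LENS-B", "LENS-C")}
        model = train_stacker(
            "rfr", train, consts, FeatureSet(STANDARD_FEATURES),
            grid={"n_estimators": [1], "max_depth": [None], "bootstrap": [False]},
            cv_folds=3, seed=0,
        )
        pred = predict_stacker(model, train, consts)
        obs = train.to_frame()["postop_se"].to_numpy()
        assert np.abs(pred - obs).mean() < 0.25  # below the refraction noise SD

    def test_empty_cohort_predicts_empty(self, small_split, small_constants):
        train, _ = small_split
        consts = {m: small_constants["*"] for m in ("LENS-A", "LENS-B", "LENS-C")}
        model = train_stacker("gbr", train, consts, FeatureSet(STANDARD_FEATURES),
                              grid={"n_estimators": [30]}, cv_folds=3, seed=0)
        empty = train.to_frame().iloc[0:0]
        assert predict_stacker(model, empty, consts).size == 0

    def test_prediction_is_pure(self, small_split, small_constants):
        train, test = small_split
        consts = {m: small_constants["*"] for m in ("LENS-A", "LENS-B", "LENS-C")}
        model = train_stacker("svr", train, consts, FeatureSet(STANDARD_FEATURES),
                              grid={"C": [1.0]}, cv_folds=3, seed=0)
        a = predict_stacker(model, test, consts)
        b = predict_stacker(model, test, consts)
        assert np.array_equal(a, b)

    def test_unseen_lens_model_rejected(self, small_split, small_constants):
        train, test = small_split
        consts = {m: small_constants["*"] for m in ("LENS-A", "LENS-B", "LENS-C")}
        model = train_stacker("gbr", train, consts, FeatureSet(STANDARD_FEATURES),
                              grid={"n_estimators": [30]}, cv_folds=3, seed=0)
        frame = test.to_frame().copy()
        frame["iol_model"] = "LENS-UNKNOWN"
        with pytest.raises(MissingConstantError):
            predict_stacker(model, frame, consts)
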