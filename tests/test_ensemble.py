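"""Ensemble weighting, prediction, disagreement CV, importance, responses."""

import numpy as np
import pandas as pd
import pytest

import traitscape as ts
from traitscape import ensemble as ens
from traitscape import learners as lrn
from traitscape.ensemble import NoSkilledLearnerError


class _ConstModel:
    """Stub learner predicting a fixed value (or a supplied function)."""

    def __init__(self, fn, predictors):
        self._fn = fn
        self.predictor_names = list(predictors)
        self.train_ranges = {p: (0.0, 1.0) for p in predictors}

    def predict(self, features):
        if callable(self._fn):
            return np.asarray(self._fn(features), dtype=float)
        return np.full(len(features), float(self._fn))


def stub_fit(kind, fn, predictions=None, predictors=("x0", "x1"),
             inner_scores=None, r2=0.5, flagged=False):
    model = None if flagged else _ConstModel(fn, predictors)
    return lrn.FitResult(
        spec=lrn.LearnerSpec(kind), model=model,
        predictions=predictions if predictions is not None else pd.DataFrame(
            columns=["row", "repetition", "predicted", "observed"]),
        pseudo_r2=r2, train_ranges=dict(model.train_ranges) if model else {},
        inner_scores=inner_scores or [], splits=[], flagged=flagged,
    )


def stub_ensemble(values, weights, predictors=("x0", "x1")):
    kinds = list(lrn.LEARNER_KINDS)[: len(values)]
    fits = {k: stub_fit(k, v, predictors=predictors)
            for k, v in zip(kinds, values)}
    return ens.EnsembleModel(trait="height", fits=fits,
                             weights=dict(zip(kinds, weights)),
                             predictors=list(predictors))


class TestWeights:
    def test_equal_scores_give_equal_weights(self):
        w = ts.ensemble_weights({"glm": 0.5, "gam": 0.5, "rf": 0.5, "brt": 0.5})
        assert all(v == pytest.approx(0.25) for v in w.values())

    def test_normalization_preserves_proportions(self):
        w = ts.ensemble_weights({"glm": 0.8, "gam": 0.0, "rf": 0.2, "brt": 0.0})
        assert w == pytest.approx({"glm": 0.8, "gam": 0.0, "rf": 0.2, "brt": 0.0})

    def test_all_zero_scores_rejected(self):
        with pytest.raises(NoSkilledLearnerError):
            ts.ensemble_weights({"glm": 0.0, "gam": 0.0, "rf": 0.0, "brt": 0.0})

    def test_weights_sum_to_one(self, height_ensemble):
        model, _, _ = height_ensemble
        assert sum(model.weights.values()) == pytest.approx(1.0, abs=1e-12)


class TestEnsemblePredict:
    def test_equal_weight_average(self):
        m = stub_ensemble([1.0, 2.0, 3.0, 4.0], [0.25] * 4)
        X = pd.DataFrame({"x0": [0.1], "x1": [0.2]})
        assert ens.ensemble_predict(m, X)[0] == pytest.approx(2.5)

    def test_degenerate_weight_recovers_single_learner(self):
        m = stub_ensemble([1.0, 2.0, 3.0, 4.0], [1.0, 0.0, 0.0, 0.0])
        X = pd.DataFrame({"x0": [0.1], "x1": [0.2]})
        assert ens.ensemble_predict(m, X)[0] == pytest.approx(1.0)

    def test_weighted_sum_example(self):
        m = stub_ensemble([10.0, 0.0, 20.0, 0.0], [0.8, 0.0, 0.2, 0.0])
        X = pd.DataFrame({"x0": [0.0], "x1": [0.0]})
        assert ens.ensemble_predict(m, X)[0] == pytest.approx(12.0)

    def test_missing_predictor_rejected(self):
        m = stub_ensemble([1.0], [1.0])
        with pytest.raises(ValueError, match="missing predictor"):
            ens.ensemble_predict(m, pd.DataFrame({"x0": [0.1]}))

    def test_prediction_bounded_by_member_predictions(self, height_ensemble):
        model, X, _ = height_ensemble
        member = ens.member_predictions(model, X)
        combined = ens.ensemble_predict(model, X)
        assert (combined >= member.min(axis=1) - 1e-9).all()
        assert (combined <= member.max(axis=1) + 1e-9).all()


class TestEnsembleCV:
    def test_identical_predictions_give_zero(self):
        assert ens.ensemble_cv([5.0, 5.0], [0.5, 0.5]) == 0.0

    def test_hand_computed_example(self):
        # ensemble 10, weighted SD 2 -> CV 0.2
        assert ens.ensemble_cv([8.0, 12.0], [0.5, 0.5]) == pytest.approx(0.2)

    def test_near_zero_ensemble_flagged_as_missing(self):
        assert np.isnan(ens.ensemble_cv([1.0, -1.0], [0.5, 0.5]))

    def test_single_positive_weight_gives_zero(self):
        assert ens.ensemble_cv([8.0, 12.0], [1.0, 0.0]) == 0.0


class TestEnsembleAccuracy:
    @staticmethod
    def prediction_table(pred, obs):
        n = len(obs)
        return pd.DataFrame({
            "row": np.tile(np.arange(n // 2), 2),
            "repetition": np.repeat([0, 1], n // 2),
            "predicted": pred, "observed": obs,
        })

    def test_identical_perfect_learners_score_one(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        fits = {k: stub_fit(k, 0.0, self.prediction_table(obs, obs),
                            inner_scores=[1.0, 1.0])
                for k in lrn.LEARNER_KINDS}
        m = ens.EnsembleModel("height", fits, {k: 0.25 for k in fits},
                              ["x0"])
        assert ens.ensemble_accuracy(m) == pytest.approx(1.0)

    def test_single_skilled_learner_recovers_its_score(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=10)
        pred = obs + 0.3 * rng.normal(size=10)
        table = self.prediction_table(pred, obs)
        fits = {"glm": stub_fit("glm", 0.0, table, inner_scores=[0.8, 0.7])}
        for k in ("gam", "rf", "brt"):
            fits[k] = stub_fit(k, 0.0, flagged=True)
        m = ens.EnsembleModel("height", fits,
                              {"glm": 1.0, "gam": 0.0, "rf": 0.0, "brt": 0.0},
                              ["x0"])
        assert ens.ensemble_accuracy(m) == ts.pseudo_r2(pred, obs)

    def test_tracks_best_learner_on_synthetic_world(self, height_ensemble):
        model, _, _ = height_ensemble
        acc = ens.ensemble_accuracy(model)
        best = max(f.pseudo_r2 for f in model.fits.values())
        assert acc >= best - 0.05


@pytest.fixture(scope="module")
def driver_fit():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.uniform(0, 1, size=(150, 3)),
                     columns=["x0", "x1", "x2"])
    y = 3.0 * X["x0"].to_numpy() + 0.01 * rng.standard_normal(150)
    return ts.cross_validate(lrn.LearnerSpec("glm"), X, y, seed=1), X


class TestPermutationImportance:

    def test_identity_permutation_scores_zero(self, driver_fit):
        fit, X = driver_fit
        imp = ts.permutation_importance(
            fit, X, permutation_func=lambda rng, n: np.arange(n))
        assert (imp.abs() < 1e-12).all()

    def test_sole_driver_high_null_low(self, driver_fit):
        fit, X = driver_fit
        imp = ts.permutation_importance(fit, X, seed=0)
        assert imp["x0"] >= 0.8
        assert imp[["x1", "x2"]].max() <= 0.1

    def test_constant_model_warns_and_scores_zero(self):
        fits = stub_fit("glm", 2.0)
        X = pd.DataFrame({"x0": np.arange(12.0), "x1": np.arange(12.0)})
        with pytest.warns(UserWarning, match="constant"):
            imp = ts.permutation_importance(fits, X)
        assert (imp == 0.0).all()


class TestEnsembleImportance:
    def test_agreement_gives_zero_spread(self):
        imp = {k: pd.Series({"x0": 0.5, "x1": 0.1})
               for k in lrn.LEARNER_KINDS}
        table = ts.ensemble_importance(imp, {k: 0.25 for k in imp})
        assert (table["cv"] == 0.0).all()
        assert table.loc["x0", "ensemble"] == pytest.approx(0.5)

    def test_degenerate_weights_recover_single_learner(self):
        imp = {"glm": pd.Series({"x0": 0.9}), "gam": pd.Series({"x0": 0.2})}
        table = ts.ensemble_importance(imp, {"glm": 1.0, "gam": 0.0})
        assert table.loc["x0", "ensemble"] == pytest.approx(0.9)

    def test_hand_computed_weighted_cv(self):
        imp = {"glm": pd.Series({"x0": 0.2}), "gam": pd.Series({"x0": 0.6})}
        table = ts.ensemble_importance(imp, {"glm": 0.5, "gam": 0.5})
        assert table.loc["x0", "ensemble"] == pytest.approx(0.4)
        assert table.loc["x0", "cv"] == pytest.approx(0.5)  # SD 0.2 / mean 0.4


class TestPartialResponse:
    def test_recovers_linear_slope(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(0, 1, size=(300, 3)),
                         columns=["x0", "x1", "x2"])
        y = 2.0 * X["x0"].to_numpy() + 0.05 * rng.standard_normal(300)
        fits = {
            kind: ts.cross_validate(lrn.LearnerSpec(kind, seed=i), X, y, seed=2)
            for i, kind in enumerate(lrn.LEARNER_KINDS)
        }
        model = ts.build_ensemble("height", fits)
        pr = ts.partial_response(model, X, "x0")
        t = pr.table
        inner = t.iloc[5:-5]  # central 80% of the range
        slope = np.polyfit(inner["focal_value"], inner["response"], 1)[0]
        assert 1.8 <= slope <= 2.2

    def test_constant_target_gives_flat_curve_with_zero_band(self):
        X = pd.DataFrame({"x0": np.linspace(0, 1, 40),
                          "x1": np.linspace(1, 0, 40)})
        m = stub_ensemble([3.7, 3.7], [0.5, 0.5], predictors=("x0", "x1"))
        pr = ts.partial_response(m, X, "x0")
        assert pr.table["response"].max() - pr.table["response"].min() < 1e-9
        assert (pr.table["cv"].abs() < 1e-12).all()

    def test_points_beyond_training_range_flagged(self):
        X = pd.DataFrame({"x0": np.linspace(0, 2, 30),
                          "x1": np.linspace(0, 1, 30)})
        m = stub_ensemble([1.0, 2.0], [0.5, 0.5])  # train ranges are [0, 1]
        pr = ts.partial_response(m, X, "x0", margin=0.1)
        t = pr.table
        inside = (t["focal_value"] >= 0.0) & (t["focal_value"] <= 1.0)
        assert t.loc[~inside, "extrapolated"].all()
        assert not t.loc[inside, "extrapolated"].any()

    def test_unknown_focal_predictor_rejected(self):
        m = stub_ensemble([1.0], [1.0])
        with pytest.raises(ValueError, match="not in model"):
            ts.partial_response(m, pd.DataFrame({"x0": [0.1], "x1": [0.2]}),
                                "bogus")


class TestPredictMaps:
    def test_masked_cells_missing_and_deterministic(self, small_world,
                                                    height_ensemble):
        stack, _, _, _ = small_world
        model, _, _ = height_ensemble
        masked = ts.PredictorStack(
            grid=stack.grid,
            layers={k: v.copy() for k, v in stack.layers.items()},
            mask=stack.mask.copy(),
        )
        masked.mask[0, 0] = False
        pred1, cv1 = ts.predict_maps(model, masked)
        pred2, cv2 = ts.predict_maps(model, masked)
        np.testing.assert_array_equal(pred1, pred2)
        np.testing.assert_array_equal(cv1, cv2)
        assert np.isnan(pred1[0, 0]) and np.isnan(cv1[0, 0])
        assert np.isfinite(pred1[stack.mask & masked.mask]).all()

    def test_absent_predictor_rejected(self, small_world):
        stack, _, _, _ = small_world
        m = stub_ensemble([1.0], [1.0], predictors=("nope",))
        with pytest.raises(ValueError, match="absent"):
            ts.predict_maps(m, stack)
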