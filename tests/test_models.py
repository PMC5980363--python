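"""The five model families behind the common fit/predict contract."""

import numpy as np
import pandas as pd
import pytest

from rangeshift.evaluation import roc_auc
from rangeshift.models import (
    FAMILIES,
    ModelSpec,
    fit_model,
    predict_surface,
    score_table,
    variable_importance,
)
from rangeshift.raster import RasterStack
from tests.conftest import make_grid

#: small hyperparameters so unit tests stay quick; contracts are unchanged
FAST = {
    "glm_stepwise": {},
    "mars": {"n_knots": 7},
    "brt": {"max_trees": 300, "learning_rate": 0.05},
    "rf": {"n_trees": 100},
    "maxent_like": {"n_knots": 4, "cv_folds": 3},
}


def toy_table(n=120, p=3, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if informative:
        logit = 2.5 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    else:
        y = rng.integers(0, 2, n)
    if y.sum() in (0, n):  # ensure both classes
        y[0] = 1 - y[0]
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["response"] = y
    df["role"] = np.where(rng.random(n) < 0.7, "train", "test")
    return df


@pytest.mark.parametrize("family", FAMILIES)
def test_separable_table_reaches_training_auc_one(family):
    rng = np.random.default_rng(1)
    n = 120
    x = np.concatenate([rng.uniform(0.5, 2, n // 2), rng.uniform(-2, -0.5, n // 2)])
    df = pd.DataFrame({"x0": x, "x1": rng.normal(size=n)})
    df["response"] = (x > 0).astype(int)
    df["role"] = "train"
    m = fit_model(ModelSpec(family, hyperparameters=FAST[family], seed=0), df)
    p, b = score_table(m, df, "train")
    assert roc_auc(p, b) == 1.0


@pytest.mark.parametrize("family", FAMILIES)
def test_predictions_bounded_and_deterministic(family):
    df = toy_table(seed=2)
    spec = ModelSpec(family, hyperparameters=FAST[family], seed=7)
    m1 = fit_model(spec, df)
    m2 = fit_model(spec, df)
    X = df[[c for c in df.columns if c.startswith("x")]]
    p1, p2 = m1.predict(X), m2.predict(X)
    assert np.all((p1 >= 0) & (p1 <= 1))
    assert np.array_equal(p1, p2)


@pytest.mark.parametrize("family", ["rf", "maxent_like"])
def test_shuffled_labels_give_null_auc(family):
    """With response independent of predictors, held-out AUC hovers at 0.5."""
    aucs = []
    for seed in range(20):
        df = toy_table(n=200, seed=seed, informative=False)
        m = fit_model(ModelSpec(family, hyperparameters=FAST[family], seed=seed), df)
        p, b = score_table(m, df, "test")
        aucs.append(roc_auc(p, b))
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_stepwise_recovers_informative_predictor():
    """One informative predictor among five pure-noise columns is retained
    by AIC stepwise in at least 9 of 10 seeds."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 400
        X = rng.normal(size=(n, 6))
        y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * X[:, 0]))).astype(int)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(6)])
        df["response"] = y
        df["role"] = "train"
        m = fit_model(ModelSpec("glm_stepwise", seed=seed), df)
        hits += "x0" in m.detail["selected"]
    assert hits >= 9


def test_rejects_single_class_table():
    df = toy_table(seed=3)
    df["response"] = 1
    with pytest.raises(ValueError, match="both"):
        fit_model(ModelSpec("rf", hyperparameters=FAST["rf"]), df)


def test_predict_rejects_missing_predictor():
    df = toy_table(seed=4)
    m = fit_model(ModelSpec("rf", hyperparameters=FAST["rf"]), df)
    with pytest.raises(KeyError, match="x2"):
        m.predict(df[["x0", "x1"]])


class TestPredictSurface:
    def _stack(self, vals_by_name):
        return RasterStack(
            [make_grid(v, west=0, north=4, cell=1.0, name=k) for k, v in vals_by_name.items()]
        )

    def test_constant_stack_gives_constant_surface(self):
        df = toy_table(seed=5)
        m = fit_model(ModelSpec("maxent_like", hyperparameters=FAST["maxent_like"]), df)
        stack = self._stack({f"x{i}": np.full((4, 4), 0.3) for i in range(3)})
        surf = predict_surface(m, stack)
        assert np.allclose(surf.values, surf.values[0, 0])

    def test_surface_matches_pointwise_contract(self):
        df = toy_table(seed=6)
        m = fit_model(ModelSpec("rf", hyperparameters=FAST["rf"]), df)
        rng = np.random.default_rng(0)
        vals = {f"x{i}": rng.normal(size=(4, 4)) for i in range(3)}
        stack = self._stack(vals)
        surf = predict_surface(m, stack)
        X = np.column_stack([vals[f"x{i}"].ravel() for i in range(3)])
        assert np.allclose(surf.values.ravel(), m.predict(X))

    def test_nodata_propagates(self):
        df = toy_table(seed=7)
        m = fit_model(ModelSpec("rf", hyperparameters=FAST["rf"]), df)
        vals = {f"x{i}": np.zeros((4, 4)) for i in range(3)}
        vals["x1"][2, 2] = -9999.0
        surf = predict_surface(m, self._stack(vals))
        assert surf.mask[2, 2]

    def test_missing_layer_named_in_error(self):
        df = toy_table(seed=8)
        m = fit_model(ModelSpec("rf", hyperparameters=FAST["rf"]), df)
        stack = self._stack({"x0": np.zeros((4, 4)), "x1": np.zeros((4, 4))})
        with pytest.raises(KeyError, match="x2"):
            predict_surface(m, stack)

    def test_warming_reduces_cold_optimum_suitability(self):
        # species with a cold Gaussian optimum on its only driver: a +5
        # uniform shift must strictly lower mean predicted suitability
        rng = np.random.default_rng(9)
        n = 600
        t = rng.uniform(-20, 0, n)
        suit = np.exp(-0.5 * ((t + 12) / 2.0) ** 2)
        y = (rng.random(n) < suit).astype(int)
        if y.sum() < 10:
            y[:10] = 1
        df = pd.DataFrame({"temp": t, "noise": rng.normal(size=n)})
        df["response"] = y
        df["role"] = "train"
        m = fit_model(ModelSpec("mars", hyperparameters=FAST["mars"], seed=0), df)
        base = {"temp": np.full((5, 5), -12.0), "noise": np.zeros((5, 5))}
        warm = {"temp": np.full((5, 5), -7.0), "noise": np.zeros((5, 5))}
        s0 = predict_surface(m, self._stack(base)).values.mean()
        s1 = predict_surface(m, self._stack(warm)).values.mean()
        assert s1 < s0


class TestImportance:
    def test_null_predictor_near_zero(self):
        df = toy_table(n=400, seed=10)
        m = fit_model(ModelSpec("rf", hyperparameters=FAST["rf"], seed=0), df)
        imp = dict(variable_importance(m, df, n_permutations=20, seed=0))
        assert abs(imp["x2"]) < 0.05

    def test_single_driver_ranked_first(self):
        df = toy_table(n=400, seed=11)
        m = fit_model(ModelSpec("maxent_like", hyperparameters=FAST["maxent_like"], seed=0), df)
        ranked = variable_importance(m, df, n_permutations=5, seed=0)
        assert ranked[0][0] == "x0"
        assert ranked[0][1] > max(v for _, v in ranked[1:])

    def test_zero_permutations_rejected(self):
        df = toy_table(seed=12)
        m = fit_model(ModelSpec("rf", hyperparameters=FAST["rf"]), df)
        with pytest.raises(ValueError):
            variable_importance(m, df, n_permutations=0)
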