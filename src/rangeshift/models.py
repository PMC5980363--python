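"""Five presence/background niche-model families behind one fit/predict
contract.

Families
--------
glm_stepwise
    Logistic regression with bidirectional AIC stepwise selection over
    linear and quadratic candidate terms (quadratics let the GLM express
    unimodal niche responses).
mars
    Multivariate adaptive regression splines: forward hinge-basis selection
    with generalized-cross-validation pruning, refit as a logistic model on
    the selected basis.
brt
    Stagewise gradient-boosted trees; tree count chosen by held-out
    deviance minimum.
rf
    Bootstrap-aggregated classification trees with per-split feature
    subsampling; suitability is the class-1 vote fraction.
maxent_like
    L1-penalized logistic regression on a linear + quadratic + hinge
    feature expansion of presence vs background — the maxnet-style
    equivalence of maximum-entropy modeling.

Background rows are down-weighted so presences and background carry equal
total weight in the likelihood-based families (glm_stepwise, mars,
maxent_like), the common presence/background convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from rangeshift.evaluation import roc_auc
from rangeshift.predictors import predictor_columns
from rangeshift.raster import RasterGrid, RasterStack

FAMILIES = ("glm_stepwise", "mars", "brt", "rf", "maxent_like")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "glm_stepwise": {"max_steps": 60},
    "mars": {"max_terms": 21, "n_knots": 15, "gcv_penalty": 3.0},
    "brt": {
        "learning_rate": 0.01,
        "max_depth": 3,
        "max_trees": 2000,
        "validation_fraction": 0.2,
        "n_iter_no_change": 25,
    },
    "rf": {"n_trees": 500, "min_samples_leaf": 1},
    "maxent_like": {"n_knots": 8, "cv_folds": 5, "c_grid": (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)},
}


@dataclass(frozen=True)
class ModelSpec:
    """Family choice plus hyperparameters; every stochastic family is seeded."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")

    def params(self) -> dict:
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        return merged


@dataclass
class FittedModel:
    """A trained family exposing suitability prediction in [0, 1]."""

    spec: ModelSpec
    predictor_names: list[str]
    _predict_fn: Callable[[np.ndarray], np.ndarray]
    detail: dict = field(default_factory=dict)

    @property
    def family(self) -> str:
        return self.spec.family

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Suitability for each row; rejects tables missing a training predictor."""
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.predictor_names if n not in X.columns]
            if missing:
                raise KeyError(f"missing predictor(s) {missing}")
            X = X[self.predictor_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.predictor_names):
            raise ValueError(
                f"expected {len(self.predictor_names)} predictor columns, got shape {X.shape}"
            )
        p = np.asarray(self._predict_fn(X), dtype=float)
        return np.clip(p, 0.0, 1.0)


def _training_arrays(table: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    train = table[table["role"] == "train"] if "role" in table.columns else table
    X = train[predictors].to_numpy(dtype=float)
    y = train["response"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both presences and background")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite predictor values in training table")
    # equal total weight on each class
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    w = np.where(y == 1, 1.0, n1 / n0)
    return X, y, w


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# --------------------------------------------------------------------------
# glm_stepwise

def _fit_glm_stepwise(X, y, w, predictors, params, seed):
    import statsmodels.api as sm

    # candidate terms: each predictor linear and squared (standardized so
    # squares stay numerically tame)
    mu = X.mean(axis=0)
    sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Z = (X - mu) / sd
    terms = [("lin", j) for j in range(X.shape[1])] + [("sq", j) for j in range(X.shape[1])]

    def columns(Zm: np.ndarray, cols: tuple[int, ...]) -> np.ndarray:
        out = [np.ones(len(Zm))]
        for c in cols:
            kind, j = terms[c]
            out.append(Zm[:, j] if kind == "lin" else Zm[:, j] ** 2)
        return np.column_stack(out)

    def fit_subset(cols: tuple[int, ...]):
        design = columns(Z, cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=200)
        return res

    current: tuple[int, ...] = ()
    best = fit_subset(current)
    best_aic = best.aic
    for _ in range(int(params["max_steps"])):
        moves = []
        for j in range(len(terms)):
            if j not in current:
                moves.append(tuple(sorted(current + (j,))))
        for j in current:
            moves.append(tuple(k for k in current if k != j))
        improved = False
        for cols in moves:
            try:
                res = fit_subset(cols)
            except Exception:
                continue
            if res.aic < best_aic - 1e-9:
                best, best_aic, current = res, res.aic, cols
                improved = True
        if not improved:
            break
    cols, res = current, best

    def predict(Xnew: np.ndarray) -> np.ndarray:
        Znew = (Xnew - mu) / sd
        return np.asarray(res.predict(columns(Znew, cols)))

    selected = sorted({predictors[terms[c][1]] for c in cols})
    selected_terms = [
        predictors[terms[c][1]] + ("^2" if terms[c][0] == "sq" else "") for c in cols
    ]
    return predict, {"selected": selected, "terms": selected_terms, "aic": float(best_aic)}


# --------------------------------------------------------------------------
# mars

def _hinge_pair(x: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    return np.maximum(0.0, x - t), np.maximum(0.0, t - x)


def _weighted_lstsq_sse(B: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
    resid = y - B @ coef
    return coef, float(np.sum(w * resid**2))


def _fit_mars(X, y, w, predictors, params, seed):
    n, p = X.shape
    max_terms = int(params["max_terms"])
    n_knots = int(params["n_knots"])
    d = float(params["gcv_penalty"])

    # candidate knots at interior quantiles of each predictor
    knot_sets = []
    for j in range(p):
        qs = np.quantile(X[:, j], np.linspace(0.05, 0.95, n_knots))
        knot_sets.append(np.unique(qs))

    basis_cols = [np.ones(n)]
    basis_desc: list[tuple[int, float, int] | None] = [None]  # (predictor, knot, sign)
    _, sse = _weighted_lstsq_sse(np.column_stack(basis_cols), y, w)
    used: set[tuple[int, float]] = set()
    while len(basis_cols) + 2 <= max_terms:
        best = None
        for j in range(p):
            for t in knot_sets[j]:
                if (j, t) in used:
                    continue
                hp, hm = _hinge_pair(X[:, j], t)
                B = np.column_stack(basis_cols + [hp, hm])
                _, cand_sse = _weighted_lstsq_sse(B, y, w)
                if best is None or cand_sse < best[0]:
                    best = (cand_sse, j, t, hp, hm)
        if best is None or best[0] > sse * (1 - 1e-4):
            break
        sse, j, t, hp, hm = best
        basis_cols += [hp, hm]
        basis_desc += [(j, float(t), +1), (j, float(t), -1)]
        used.add((j, t))

    # backward pruning by generalized cross-validation
    def gcv(B: np.ndarray) -> float:
        _, s = _weighted_lstsq_sse(B, y, w)
        m = B.shape[1]
        c = m + d * max(m - 1, 0) / 2.0
        denom = (1.0 - c / n) ** 2
        return np.inf if denom <= 0 else s / n / denom

    keep = list(range(len(basis_cols)))
    Bfull = np.column_stack(basis_cols)
    best_keep, best_gcv = list(keep), gcv(Bfull[:, keep])
    while len(keep) > 1:
        cand = None
        for k in keep[1:]:  # never drop the intercept
            sub = [i for i in keep if i != k]
            g = gcv(Bfull[:, sub])
            if cand is None or g < cand[0]:
                cand = (g, sub)
        keep = cand[1]
        if cand[0] < best_gcv:
            best_gcv, best_keep = cand[0], list(keep)

    kept_desc = [basis_desc[i] for i in best_keep if basis_desc[i] is not None]

    def build_basis(Xnew: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(Xnew))]
        for j, t, sign in kept_desc:
            h = np.maximum(0.0, (Xnew[:, j] - t) * sign)
            cols.append(h)
        return np.column_stack(cols)

    # logistic refit on the pruned basis
    from sklearn.linear_model import LogisticRegression

    Bsel = build_basis(X)
    lr = LogisticRegression(C=1e6, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(Bsel[:, 1:] if Bsel.shape[1] > 1 else np.zeros((n, 1)), y, sample_weight=w)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        B = build_basis(Xnew)
        feats = B[:, 1:] if B.shape[1] > 1 else np.zeros((len(Xnew), 1))
        return lr.predict_proba(feats)[:, 1]

    terms = [(predictors[j], t, sign) for j, t, sign in kept_desc]
    return predict, {"terms": terms, "gcv": float(best_gcv)}


# --------------------------------------------------------------------------
# brt

def _fit_brt(X, y, w, predictors, params, seed):
    from sklearn.ensemble import GradientBoostingClassifier

    gb = GradientBoostingClassifier(
        learning_rate=float(params["learning_rate"]),
        max_depth=int(params["max_depth"]),
        n_estimators=int(params["max_trees"]),
        validation_fraction=float(params["validation_fraction"]),
        n_iter_no_change=int(params["n_iter_no_change"]),
        random_state=seed,
    )
    gb.fit(X, y)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return gb.predict_proba(Xnew)[:, 1]

    return predict, {"n_trees": int(gb.n_estimators_)}


# --------------------------------------------------------------------------
# rf

def _fit_rf(X, y, w, predictors, params, seed):
    from sklearn.ensemble import RandomForestClassifier

    rf = RandomForestClassifier(
        n_estimators=int(params["n_trees"]),
        max_features="sqrt",
        min_samples_leaf=int(params["min_samples_leaf"]),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y)
    # out-of-bag votes are the forest's honest training-row scores; in-bag
    # votes memorize their rows and would miscalibrate any threshold
    oob = rf.oob_decision_function_[:, 1]
    oob = np.where(np.isnan(oob), 0.5, oob)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return rf.predict_proba(Xnew)[:, 1]

    return predict, {"n_trees": int(params["n_trees"]), "oob_train_scores": oob}


# --------------------------------------------------------------------------
# maxent_like

def _fit_maxent_like(X, y, w, predictors, params, seed):
    from sklearn.linear_model import LogisticRegressionCV

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    n_knots = int(params["n_knots"])
    knots = [lo + span * q for q in np.linspace(0.1, 0.9, n_knots)]

    def expand(Xnew: np.ndarray) -> np.ndarray:
        Z = (Xnew - lo) / span
        feats = [Z, Z**2]
        for t in knots:
            T = (t - lo) / span
            feats.append(np.maximum(0.0, Z - T))
            feats.append(np.maximum(0.0, T - Z))
        return np.hstack(feats)

    F = expand(X)
    lr = LogisticRegressionCV(
        Cs=list(params["c_grid"]),
        cv=int(params["cv_folds"]),
        penalty="l1",
        solver="liblinear",
        max_iter=300,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(F, y, sample_weight=w)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return lr.predict_proba(expand(Xnew))[:, 1]

    n_active = int(np.sum(lr.coef_ != 0))
    return predict, {"n_features": F.shape[1], "n_active": n_active, "C": float(lr.C_[0])}


_FITTERS = {
    "glm_stepwise": _fit_glm_stepwise,
    "mars": _fit_mars,
    "brt": _fit_brt,
    "rf": _fit_rf,
    "maxent_like": _fit_maxent_like,
}


def fit_model(spec: ModelSpec, table: pd.DataFrame, predictors: list[str] | None = None) -> FittedModel:
    """Fit one family on the table's training rows.

    ``predictors`` defaults to every non-coordinate, non-bookkeeping column.
    """
    predictors = predictors or predictor_columns(table)
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    X, y, w = _training_arrays(table, predictors)
    predict_fn, detail = _FITTERS[spec.family](X, y, w, predictors, spec.params(), spec.seed)
    return FittedModel(spec=spec, predictor_names=list(predictors), _predict_fn=predict_fn, detail=detail)


def predict_surface(model: FittedModel, stack: RasterStack, scenario_id: str = "present") -> RasterGrid:
    """Cell-wise suitability surface; nodata propagates from any input layer."""
    missing = [n for n in model.predictor_names if n not in stack]
    if missing:
        raise KeyError(f"stack is missing predictor layer(s) {missing}")
    grid = stack.grid
    bad = stack.combined_mask(model.predictor_names)
    ok = ~bad
    X = np.column_stack([stack[n].values[ok] for n in model.predictor_names])
    out = np.full(grid.shape, grid.nodata)
    out[ok] = model.predict(X)
    surface = grid.with_values(out, name=f"{model.family}_{scenario_id}")
    return surface


def score_table(model: FittedModel, table: pd.DataFrame, role: str) -> tuple[np.ndarray, np.ndarray]:
    """(presence scores, background scores) for rows with the given role.

    For random forests the training rows are scored out-of-bag (aligned
    with the fitting order), so thresholds calibrated on them transfer to
    held-out data instead of reflecting in-bag memorization.
    """
    sub = table[table["role"] == role] if "role" in table.columns else table
    oob = model.detail.get("oob_train_scores")
    if role == "train" and oob is not None and len(oob) == len(sub):
        scores = np.asarray(oob, dtype=float)
    else:
        scores = model.predict(sub)
    y = sub["response"].to_numpy(dtype=int)
    return scores[y == 1], scores[y == 0]


def variable_importance(
    model: FittedModel,
    table: pd.DataFrame,
    n_permutations: int = 5,
    seed: int = 0,
    role: str = "test",
) -> list[tuple[str, float]]:
    """Permutation importance: mean drop in AUC when one predictor's column
    is shuffled, averaged over ``n_permutations``; sorted descending."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sub = table[table["role"] == role] if "role" in table.columns else table
    if sub.empty:
        sub = table
    y = sub["response"].to_numpy(dtype=int)
    X = sub[model.predictor_names].to_numpy(dtype=float)
    base_scores = model.predict(X)
    base_auc = roc_auc(base_scores[y == 1], base_scores[y == 0])
    rng = np.random.default_rng(seed)
    out = []
    for j, name in enumerate(model.predictor_names):
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = model.predict(Xp)
            drops.append(base_auc - roc_auc(s[y == 1], s[y == 0]))
        out.append((name, float(np.mean(drops))))
    out.sort(key=lambda kv: -kv[1])
    return out
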