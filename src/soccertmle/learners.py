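"""Base-learner library for the super learner.

Each learner is a tiny adapter with ``fit(X, y)`` / ``predict(X)`` and a
``name``.  For a ``"regression"`` task ``predict`` returns conditional-mean
estimates; for a ``"probability"`` task it returns ``P(y=1 | X)`` clipped to
``[PROB_CLIP, 1 - PROB_CLIP]``.  The rosters mirror the usual targeted
learning libraries: a marginal mean, (logistic-)linear models with and
without pairwise interactions, forward-stepwise AIC selection, a spline
additive model, a random forest and a single decision tree.
"""

from __future__ import annotations

import itertools

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = ["PROB_CLIP", "Learner", "build_library", "ROSTERS"]

#: clip applied to every probability-scale prediction
PROB_CLIP = 1e-6


def _as_2d(X):
    X = np.asarray(X, dtype=float)
    return X.reshape(-1, 1) if X.ndim == 1 else X


class Learner:
    """Named wrapper exposing a uniform fit/predict pair.

    ``model_factory`` builds a fresh underlying model per fit so a learner
    instance can be reused across CV folds without state leakage.
    """

    def __init__(self, name, model_factory, task, transform=None):
        self.name = name
        self.task = task
        self._factory = model_factory
        self._transform = transform
        self._model = None

    def fit(self, X, y):
        X = _as_2d(X)
        if self._transform is not None:
            X = self._transform(X)
        self._model = self._factory()
        self._model.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        if self._model is None:
            raise RuntimeError(f"learner {self.name!r} is not fitted")
        X = _as_2d(X)
        if self._transform is not None:
            X = self._transform(X)
        if self.task == "probability":
            if hasattr(self._model, "predict_proba"):
                p = self._model.predict_proba(X)[:, -1]
            else:
                p = self._model.predict(X)
            return np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
        return np.asarray(self._model.predict(X), dtype=float)


class _MeanModel:
    """Marginal mean / marginal rate; the fallback learner."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y)) if len(y) else 0.0
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class _StepwiseModel:
    """Forward stepwise selection by AIC over main effects (optionally plus
    pairwise interaction terms), in the spirit of R's step().

    Gaussian family for regression, binomial for probability.
    """

    def __init__(self, task, interactions=False, max_terms=None):
        self.task = task
        self.interactions = interactions
        self.max_terms = max_terms

    def _terms(self, X):
        p = X.shape[1]
        cols = [(j,) for j in range(p)]
        if self.interactions:
            cols += list(itertools.combinations(range(p), 2))
        return cols

    @staticmethod
    def _design(X, terms):
        mats = [np.ones((X.shape[0], 1))]
        for t in terms:
            col = X[:, t[0]] if len(t) == 1 else X[:, t[0]] * X[:, t[1]]
            mats.append(col.reshape(-1, 1))
        return np.hstack(mats)

    def _fit_one(self, X, y, terms):
        D = self._design(X, terms)
        if self.task == "probability":
            fam = sm.families.Binomial()
        else:
            fam = sm.families.Gaussian()
        with np.errstate(all="ignore"):
            res = sm.GLM(y, D, family=fam).fit(maxiter=50)
        return res

    def fit(self, X, y):
        candidates = self._terms(X)
        selected = []
        res = self._fit_one(X, y, selected)
        best_aic = res.aic
        limit = self.max_terms or len(candidates)
        improved = True
        while improved and len(selected) < limit:
            improved = False
            best_term, best_res = None, None
            for t in candidates:
                if t in selected:
                    continue
                try:
                    cand = self._fit_one(X, y, selected + [t])
                except Exception:
                    continue
                if np.isfinite(cand.aic) and cand.aic < best_aic - 1e-9:
                    best_aic, best_term, best_res = cand.aic, t, cand
            if best_term is not None:
                selected.append(best_term)
                res = best_res
                improved = True
        self.terms_, self.result_ = selected, res
        return self

    def predict(self, X):
        D = self._design(np.asarray(X, dtype=float), self.terms_)
        return np.asarray(self.result_.predict(D), dtype=float)


def _spline_pipeline(task, seed):
    # additive: one cubic spline basis per feature, no cross terms
    spline = SplineTransformer(n_knots=5, degree=3, include_bias=False)
    if task == "probability":
        return make_pipeline(spline, StandardScaler(), LogisticRegression(max_iter=1000))
    return make_pipeline(spline, LinearRegression())


def _interaction_pipeline(task, degree, interaction_only):
    poly = PolynomialFeatures(
        degree=degree, interaction_only=interaction_only, include_bias=False
    )
    if task == "probability":
        return make_pipeline(poly, StandardScaler(), LogisticRegression(max_iter=1000))
    return make_pipeline(poly, LinearRegression())


def _make(name, task, seed):
    rf_cls = RandomForestClassifier if task == "probability" else RandomForestRegressor
    tree_cls = DecisionTreeClassifier if task == "probability" else DecisionTreeRegressor
    factories = {
        "mean": lambda: _MeanModel(),
        "glm": (
            (lambda: LogisticRegression(max_iter=1000))
            if task == "probability"
            else (lambda: LinearRegression())
        ),
        "glm_interaction": lambda: _interaction_pipeline(task, 2, True),
        "poly2": lambda: _interaction_pipeline(task, 2, False),
        "step": lambda: _StepwiseModel(task, interactions=False),
        "step_interaction": lambda: _StepwiseModel(task, interactions=True),
        "spline_additive": lambda: _spline_pipeline(task, seed),
        "random_forest": lambda: rf_cls(
            n_estimators=100, min_samples_leaf=20, random_state=seed, n_jobs=1
        ),
        "tree": lambda: tree_cls(min_samples_leaf=20, random_state=seed),
    }
    if name not in factories:
        raise KeyError(f"unknown learner {name!r}; available: {sorted(factories)}")
    return Learner(name, factories[name], task)


#: named roster presets; "handpicked" mirrors the glm / glm.interaction /
#: step / step.interaction / gam / randomForest / rpart style library,
#: "default" is the package's standard library, the "fast" variants are
#: reduced rosters for replicated simulation studies.
ROSTERS = {
    "default": [
        "mean",
        "glm",
        "glm_interaction",
        "poly2",
        "spline_additive",
        "random_forest",
        "tree",
    ],
    "handpicked": [
        "glm",
        "glm_interaction",
        "step",
        "step_interaction",
        "spline_additive",
        "random_forest",
        "tree",
    ],
    "fast": ["mean", "glm", "poly2"],
    "fast_handpicked": ["glm", "glm_interaction", "tree"],
    "parametric": ["glm"],
}


def build_library(roster="default", task="regression", seed=0):
    """Instantiate a list of learners from a preset name or list of names."""
    if task not in ("regression", "probability"):
        raise ValueError("task must be 'regression' or 'probability'")
    names = ROSTERS[roster] if isinstance(roster, str) else list(roster)
    if len(set(names)) != len(names):
        raise ValueError("learner names must be unique")
    return [_make(n, task, seed) for n in names]
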