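"""V-fold cross-validation engine and discrete/continuous super learner.

The super learner evaluates every base learner by V-fold cross-validation,
then either picks the learner with the lowest mean validation risk (the
*discrete* super learner) or finds convex weights over the library that
minimise the cross-validated risk of the weighted ensemble (the
*continuous* super learner).  Weights are obtained by non-negative least
squares on the stacked validation predictions, renormalised to the simplex;
for probability tasks the loss is the negative Bernoulli log-likelihood but
the same NNLS weight solver is used on the predicted probabilities, which
is standard ensemble practice.

A base learner that fails to fit on some fold is replaced, for that fold,
by the marginal-mean learner so that one fragile learner cannot abort the
ensemble; failures are counted and reported.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator

from .learners import PROB_CLIP, ROSTERS, Learner, _MeanModel, build_library

__all__ = [
    "make_folds",
    "cv_risks",
    "discrete_sl",
    "continuous_sl_weights",
    "sl_fit_predict",
    "SuperLearner",
]


def make_folds(n: int, v: int, seed=0) -> np.ndarray:
    """Random V-fold partition; returns per-observation fold labels in 1..V.

    Every observation falls in the validation set of exactly one fold and is
    used V-1 times for training; fold sizes differ by at most one.
    """
    if v < 2 or v > n:
        raise ValueError(f"need 2 <= V <= n, got V={v}, n={n}")
    rng = np.random.default_rng(seed)
    labels = 1 + (np.arange(n) % v)
    return labels[rng.permutation(n)]


def _loss(task, y, pred):
    if task == "probability":
        p = np.clip(pred, PROB_CLIP, 1 - PROB_CLIP)
        return -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return (y - pred) ** 2


def _cv_predictions(library, folds, X, y, task):
    """Out-of-fold predictions for each learner; m x n matrix.

    Returns (cv_pred, risks m x V, n_failures).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and target are not row-aligned")
    v = int(folds.max())
    m = len(library)
    cv_pred = np.empty((m, len(y)))
    risks = np.empty((m, v))
    failures = 0
    for fold in range(1, v + 1):
        val = folds == fold
        Xtr, ytr, Xval = X[~val], y[~val], X[val]
        fallback = None
        for j, lrn in enumerate(library):
            try:
                pred = lrn.fit(Xtr, ytr).predict(Xval)
                if not np.all(np.isfinite(pred)):
                    raise FloatingPointError("non-finite predictions")
            except Exception:
                failures += 1
                if fallback is None:
                    fallback = _MeanModel().fit(Xtr, ytr)
                pred = fallback.predict(Xval)
                if task == "probability":
                    pred = np.clip(pred, PROB_CLIP, 1 - PROB_CLIP)
            cv_pred[j, val] = pred
            risks[j, fold - 1] = float(np.mean(_loss(task, y[val], pred)))
    if failures == m * v:
        raise RuntimeError("every learner failed on every fold")
    return cv_pred, risks, failures


def cv_risks(library, folds, X, y, task="regression") -> np.ndarray:
    """m x V matrix of mean validation losses (squared error or log-loss)."""
    if len(library) == 0:
        raise ValueError("empty learner library")
    _, risks, _ = _cv_predictions(library, folds, X, y, task)
    return risks


def discrete_sl(risks) -> int:
    """Index of the learner with lowest fold-averaged risk (ties: lowest index)."""
    risks = np.asarray(risks, dtype=float)
    if risks.size == 0:
        raise ValueError("empty risk matrix")
    return int(np.argmin(risks.mean(axis=1)))


def continuous_sl_weights(cv_predictions, y) -> np.ndarray:
    """Convex ensemble weights minimising cross-validated loss.

    Solves NNLS of the target on the stacked out-of-fold predictions and
    renormalises onto the simplex.  Falls back to the single best learner
    when NNLS returns the zero vector (possible for a constant target of 0).
    """
    Z = np.asarray(cv_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite predictions or target")
    if Z.ndim == 1:
        Z = Z.reshape(1, -1)
    m = Z.shape[0]
    if m == 1:
        return np.array([1.0])
    w, _ = nnls(Z.T, y)
    if w.sum() <= 0:
        w = np.zeros(m)
        w[int(np.argmin(np.mean((Z - y) ** 2, axis=1)))] = 1.0
    w = w / w.sum()
    # NNLS + renormalisation is only simplex-optimal up to scaling; polish
    # with an equality-constrained solve so vertices are never beaten
    obj = lambda a: float(np.mean((a @ Z - y) ** 2))
    jac = lambda a: 2.0 * (Z @ (a @ Z - y)) / len(y)
    res = minimize(
        obj,
        w,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    cand = np.clip(res.x, 0.0, None)
    cand = cand / cand.sum()
    if res.success and obj(cand) <= obj(w):
        w = cand
    # a vertex may still win on degenerate instances; never return worse
    vertex = np.zeros(m)
    vertex[int(np.argmin(np.mean((Z - y) ** 2, axis=1)))] = 1.0
    if obj(vertex) < obj(w):
        w = vertex
    return w


def sl_fit_predict(library, folds, X, y, new_X, task="regression"):
    """One-shot continuous super learner: weights from CV, refit on all data,
    alpha-weighted prediction on ``new_X``."""
    sl = SuperLearner(learners=[l.name for l in library], task=task)
    sl._fit_with_library(library, folds, X, y)
    return sl.predict(new_X)


class SuperLearner(BaseEstimator):
    """Cross-validated convex-ensemble regressor / probability estimator.

    Parameters
    ----------
    learners : str or list of str
        Roster preset name (see ``learners.ROSTERS``) or explicit list of
        learner names.
    task : {"regression", "probability"}
        Loss and prediction scale: squared error for conditional means,
        negative Bernoulli log-likelihood for probabilities.
    v : int
        Number of cross-validation folds.
    random_state : int
        Seed for the fold assignment and any stochastic base learner.

    Attributes
    ----------
    learner_names_ : list of str
    weights_ : ndarray, shape (m,)
        Convex ensemble weights (non-negative, sum to one).
    risks_ : ndarray, shape (m, V)
        Per-learner, per-fold validation risks.
    cv_risk_ : float
        Cross-validated risk achieved by the weighted ensemble.
    discrete_index_ : int
        Index chosen by the discrete super learner.
    n_failures_ : int
        Fold-level learner failures replaced by the marginal mean.
    """

    def __init__(self, learners="default", task="regression", v=10, random_state=0):
        self.learners = learners
        self.task = task
        self.v = v
        self.random_state = random_state

    # single-learner libraries skip CV entirely: the weights are forced
    def fit(self, X, y):
        library = build_library(self.learners, self.task, seed=self.random_state)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y, dtype=float)
        if len(library) == 1:
            folds = None
        else:
            folds = make_folds(len(y), min(self.v, len(y)), seed=self.random_state)
        return self._fit_with_library(library, folds, X, y)

    def _fit_with_library(self, library, folds, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y, dtype=float)
        self.learner_names_ = [l.name for l in library]
        m = len(library)
        if m == 1:
            self.weights_ = np.array([1.0])
            self.risks_ = np.full((1, 1), np.nan)
            self.discrete_index_ = 0
            self.n_failures_ = 0
        else:
            cv_pred, self.risks_, self.n_failures_ = _cv_predictions(
                library, folds, X, y, self.task
            )
            self.discrete_index_ = discrete_sl(self.risks_)
            self.weights_ = continuous_sl_weights(cv_pred, y)
            ens = self.weights_ @ cv_pred
            self.cv_risk_ = float(np.mean(_loss(self.task, y, ens)))
        # refit every learner on the full data for prediction
        self.fitted_learners_ = []
        fallback = _MeanModel().fit(X, y)
        for lrn in library:
            try:
                self.fitted_learners_.append(lrn.fit(X, y))
            except Exception:
                self.n_failures_ += 1
                sub = Learner(lrn.name, _MeanModel, self.task)
                sub._model = fallback
                self.fitted_learners_.append(sub)
        if m == 1:
            pred = self.fitted_learners_[0].predict(X)
            self.cv_risk_ = float(np.mean(_loss(self.task, y, pred)))
        return self

    def predict(self, X):
        if not hasattr(self, "fitted_learners_"):
            raise RuntimeError("SuperLearner is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        preds = np.vstack([l.predict(X) for l in self.fitted_learners_])
        out = self.weights_ @ preds
        if self.task == "probability":
            out = np.clip(out, PROB_CLIP, 1 - PROB_CLIP)
        return out
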