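"""G-computation (plug-in) estimation of the ATE with a parametric
linear outcome model — the classical GLM comparator.

The procedure: fit an identity-link least-squares model of the (normalised)
outcome on treatment plus the adjustment covariates, predict every row's
outcome in the two counterfactual worlds A=1 and A=0, and average the
difference over the empirical covariate distribution.  For a main-effects
linear model this plug-in estimate equals the fitted coefficient on A
exactly, so its confidence interval is the classical OLS Wald interval on
that coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .simulate import validate_table

__all__ = [
    "DegenerateDesignError",
    "OutcomeFit",
    "ATEResult",
    "fit_outcome_glm",
    "predict_counterfactuals",
    "ate_plugin",
    "GComputationATE",
]

#: named adjustment sets of the substitution analysis
ADJUSTMENTS = {"correct": ("W1", "W2", "W3"), "misspecified": ("W1", "W2")}


class DegenerateDesignError(ValueError):
    """Raised when the outcome design matrix is rank deficient."""


@dataclass
class ATEResult:
    """Point estimate with 95% interval and provenance labels."""

    estimate: float
    ci_low: float
    ci_high: float
    estimator: str = "GLM"
    adjustment: str = "custom"
    n: int = 0

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _design(data: pd.DataFrame, terms, treatment_col, treatment=None) -> np.ndarray:
    """Design matrix [1, A, terms...].

    A term is normally a column name entered as a main effect; a term of the
    form ``"A:col"`` is the treatment-by-column product, recomputed when the
    treatment is forced (needed for saturated counterfactual prediction).
    """
    a = (
        data[treatment_col].to_numpy(dtype=float)
        if treatment is None
        else np.full(len(data), float(treatment))
    )
    cols = [np.ones(len(data)), a]
    for t in terms:
        if t.startswith(f"{treatment_col}:"):
            cols.append(a * data[t.split(":", 1)[1]].to_numpy(dtype=float))
        else:
            cols.append(data[t].to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass
class OutcomeFit:
    """Fitted linear outcome model E[Y | A, W] = b0 + b1*A + b2'W."""

    terms: tuple  # adjustment covariates, in design order
    params: pd.Series = field(repr=False)  # const, A, then terms
    se_treatment: float = 0.0
    fitted: bool = False
    treatment_col: str = "A"

    def predict(self, data: pd.DataFrame, treatment=None) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("outcome model is not fitted")
        X = _design(data, self.terms, self.treatment_col, treatment)
        return X @ self.params.to_numpy()


def fit_outcome_glm(
    data: pd.DataFrame, adjustment=("W1", "W2", "W3"), outcome_col="Y", treatment_col="A"
) -> OutcomeFit:
    """Ordinary least squares of the outcome on intercept + A + adjustment terms."""
    terms = tuple(adjustment)
    if len(data) <= len(terms) + 1:
        raise ValueError(f"need more than {len(terms) + 1} rows, got {len(data)}")
    a = data[treatment_col].to_numpy(dtype=float)
    if np.all(a == a[0]):
        raise ValueError("treatment does not vary; ATE is not estimable")
    names = ["const", treatment_col, *terms]
    X = _design(data, terms, treatment_col)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the terms involved in the collinearity via the null space
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        guilty = [names[j] for j in np.where(np.any(np.abs(null) > 1e-8, axis=0))[0]]
        raise DegenerateDesignError(f"collinear design; terms involved: {guilty}")
    res = sm.OLS(data[outcome_col].to_numpy(dtype=float), X).fit()
    params = pd.Series(res.params, index=names)
    return OutcomeFit(
        terms=terms,
        params=params,
        se_treatment=float(res.bse[1]),
        fitted=True,
        treatment_col=treatment_col,
    )


def predict_counterfactuals(fit: OutcomeFit, data: pd.DataFrame):
    """Evaluate the fit with A forced to 1 and to 0; returns (y1_hat, y0_hat)."""
    return fit.predict(data, treatment=1), fit.predict(data, treatment=0)


def ate_plugin(y1_hat, y0_hat, se=None, estimator="GLM", adjustment="custom") -> ATEResult:
    """Plug-in ATE: mean counterfactual contrast over the empirical W-distribution.

    ``se`` is the standard error used for the 95% Wald interval (for the
    main-effects linear model, the OLS SE on the treatment coefficient —
    exact because the plug-in estimate then equals that coefficient).  With
    no SE available the interval degenerates to the point estimate.
    """
    y1_hat = np.asarray(y1_hat, dtype=float)
    y0_hat = np.asarray(y0_hat, dtype=float)
    if y1_hat.size == 0:
        raise ValueError("no predictions to average")
    est = float(np.mean(y1_hat - y0_hat))
    half = 1.959963984540054 * float(se) if se is not None else 0.0
    return ATEResult(est, est - half, est + half, estimator, adjustment, y1_hat.size)


class GComputationATE(BaseEstimator):
    """G-computation ATE estimator with a main-effects linear outcome model.

    Parameters
    ----------
    adjustment : tuple of str or {"correct", "misspecified"}
        Covariates entered as main effects next to the treatment.
    treatment_col, outcome_col : str
        Column names of the binary treatment and bounded outcome.

    Attributes
    ----------
    outcome_fit_ : OutcomeFit
    ate_ : float
    ci_ : (float, float)
    result_ : ATEResult
    """

    def __init__(self, adjustment="correct", treatment_col="A", outcome_col="Y"):
        self.adjustment = adjustment
        self.treatment_col = treatment_col
        self.outcome_col = outcome_col

    def _terms(self):
        if isinstance(self.adjustment, str):
            return ADJUSTMENTS[self.adjustment]
        return tuple(self.adjustment)

    def fit(self, data: pd.DataFrame, y=None):
        validate_table(data)
        label = self.adjustment if isinstance(self.adjustment, str) else "custom"
        self.outcome_fit_ = fit_outcome_glm(
            data, self._terms(), self.outcome_col, self.treatment_col
        )
        y1, y0 = predict_counterfactuals(self.outcome_fit_, data)
        self.result_ = ate_plugin(
            y1, y0, se=self.outcome_fit_.se_treatment, estimator="GLM", adjustment=label
        )
        self.ate_ = self.result_.estimate
        self.ci_ = (self.result_.ci_low, self.result_.ci_high)
        return self
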