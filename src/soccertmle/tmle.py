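"""Targeted maximum likelihood estimation of the ATE on a bounded outcome.

Starting from an initial super-learner fit of the outcome regression
Q̄(A, W) and a propensity fit g(1|W), the targeting step fluctuates the
initial fit along the clever covariate

    H(A, W) = A / g(1|W) - (1 - A) / g(0|W)

by a one-parameter, intercept-free logistic regression of Y on H with
offset logit Q̄(A, W).  On the bounded [0, 1] outcome the logistic
fluctuation keeps every targeted prediction inside (0, 1).  The fitted
fluctuation solves the efficient-influence-curve score equation
mean(H · (Y - Q̄*)) = 0, which delivers the double-robustness property;
the influence curve also supplies the sandwich standard error for Wald
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .gcomp import ADJUSTMENTS, ATEResult
from .simulate import validate_table
from .superlearner import SuperLearner

__all__ = [
    "PropensityFit",
    "CleverCovariate",
    "Fluctuation",
    "TargetedOutcome",
    "estimate_propensity",
    "clever_covariate",
    "fluctuate",
    "ate_tmle",
    "ic_variance",
    "TMLEATE",
]

_QCLIP = 1e-6  # clip on the probability scale before taking logits
_Z95 = 1.959963984540054


@dataclass
class PropensityFit:
    """Truncated per-row estimates of P(A=1 | W)."""

    g1: np.ndarray
    lb: float
    estimator: str = "SL"

    @property
    def g0(self):
        return 1.0 - self.g1


@dataclass
class CleverCovariate:
    """Signed inverse-propensity fluctuation direction per row."""

    H: np.ndarray


@dataclass
class Fluctuation:
    epsilon: float
    converged: bool
    score_residual: float


@dataclass
class TargetedOutcome:
    """Targeted counterfactual predictions, all strictly inside (0, 1)."""

    q1_star: np.ndarray
    q0_star: np.ndarray
    qa_star: np.ndarray


def estimate_propensity(
    data: pd.DataFrame,
    adjustment=("W1", "W2", "W3"),
    roster="default",
    v=10,
    lb=0.025,
    seed=0,
    treatment_col="A",
) -> PropensityFit:
    """Super-learner probability fit of the treatment on the adjustment set,
    truncated to [lb, 1-lb]."""
    if not 0 < lb < 0.5:
        raise ValueError("truncation bound must be in (0, 0.5)")
    a = data[treatment_col].to_numpy(dtype=float)
    if np.all(a == a[0]):
        raise ValueError("treatment does not vary: positivity violated globally")
    sl = SuperLearner(learners=roster, task="probability", v=v, random_state=seed)
    X = data[list(adjustment)].to_numpy(dtype=float)
    sl.fit(X, a)
    g1 = np.clip(sl.predict(X), lb, 1 - lb)
    label = roster if isinstance(roster, str) else "SL"
    fit = PropensityFit(g1=g1, lb=lb, estimator=label)
    fit.model_ = sl
    return fit


def clever_covariate(data: pd.DataFrame, g: PropensityFit, treatment_col="A") -> CleverCovariate:
    """H_i = 1/g1_i for treated rows, -1/(1-g1_i) for control rows."""
    a = data[treatment_col].to_numpy(dtype=float)
    if len(a) != len(g.g1):
        raise ValueError("propensity fit is not aligned with the data")
    H = np.where(a == 1, 1.0 / g.g1, -1.0 / g.g0)
    return CleverCovariate(H=H)


def _score(eps, y, off, H):
    return float(np.mean(H * (y - expit(off + eps * H))))


def fluctuate(
    y,
    q1,
    q0,
    qa,
    g: PropensityFit,
    H: CleverCovariate,
    max_iter=100,
    tol=1e-8,
):
    """Solve the one-dimensional logistic fluctuation.

    epsilon is the MLE of an intercept-free logistic regression of Y on H
    with offset logit(qa); Newton steps (the score is strictly decreasing
    in epsilon) with a bracketed root-finding fallback.  Targeted
    counterfactual predictions:

        q1* = expit(logit(q1) + eps / g1),  q0* = expit(logit(q0) - eps / g0).
    """
    y = np.asarray(y, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("fluctuation requires Y in [0, 1]")
    q1 = np.clip(np.asarray(q1, dtype=float), _QCLIP, 1 - _QCLIP)
    q0 = np.clip(np.asarray(q0, dtype=float), _QCLIP, 1 - _QCLIP)
    qa = np.clip(np.asarray(qa, dtype=float), _QCLIP, 1 - _QCLIP)
    Hv = H.H
    off = logit(qa)

    eps = 0.0
    converged = False
    for _ in range(max_iter):
        s = _score(eps, y, off, Hv)
        if abs(s) <= tol:
            converged = True
            break
        q = expit(off + eps * Hv)
        info = float(np.mean(Hv**2 * q * (1 - q)))
        if info <= 1e-14:
            break
        eps = eps + s / info
    if not converged:
        # monotone score: bracket and bisect
        lo, hi = -1.0, 1.0
        for _ in range(60):
            if _score(lo, y, off, Hv) < 0:
                lo *= 2
            elif _score(hi, y, off, Hv) > 0:
                hi *= 2
            else:
                break
        try:
            eps = brentq(lambda e: _score(e, y, off, Hv), lo, hi, xtol=1e-12)
            converged = abs(_score(eps, y, off, Hv)) <= 1e-6
        except ValueError:
            pass
    resid = _score(eps, y, off, Hv)
    if not converged and abs(resid) > 1e-6:
        raise RuntimeError(
            f"fluctuation did not converge: |score residual| = {abs(resid):.3g} "
            f"at epsilon = {eps:.6g}"
        )
    targeted = TargetedOutcome(
        q1_star=expit(logit(q1) + eps / g.g1),
        q0_star=expit(logit(q0) - eps / g.g0),
        qa_star=expit(off + eps * Hv),
    )
    return Fluctuation(epsilon=float(eps), converged=converged, score_residual=resid), targeted


def ate_tmle(
    targeted: TargetedOutcome, ci=None, estimator="TMLE", adjustment="custom"
) -> ATEResult:
    """Targeted plug-in ATE: mean of q1* - q0*."""
    est = float(np.mean(targeted.q1_star - targeted.q0_star))
    lo, hi = ci if ci is not None else (est, est)
    return ATEResult(est, lo, hi, estimator, adjustment, len(targeted.q1_star))


def ic_variance(y, targeted: TargetedOutcome, H: CleverCovariate, estimate, alpha=0.05):
    """Efficient-influence-curve Wald interval.

    D_i = H_i (Y_i - qa*_i) + (q1*_i - q0*_i) - estimate;
    CI = estimate +/- z * sd(D) / sqrt(n).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations for IC inference")
    D = H.H * (y - targeted.qa_star) + (targeted.q1_star - targeted.q0_star) - estimate
    se = float(np.std(D, ddof=1) / np.sqrt(n))
    return estimate - _Z95 * se, estimate + _Z95 * se


class TMLEATE(BaseEstimator):
    """Targeted maximum likelihood ATE estimator.

    Parameters
    ----------
    adjustment : tuple of str or {"correct", "misspecified"}
        Confounder set for both the outcome regression and the propensity.
    outcome_learners, propensity_learners : str or list of str
        Roster presets (see ``learners.ROSTERS``) for the two super learners.
    v : int
        Cross-validation folds.
    lb : float
        Propensity truncation bound (defaults to the conventional 0.025).
    max_iter, tol : fluctuation solver controls.
    random_state : int
        Master seed; child seeds for the outcome SL, propensity SL and folds
        are derived deterministically.

    Attributes
    ----------
    ate_ : float                 targeted point estimate (normalised scale)
    ci_ : (float, float)         IC-based 95% interval
    epsilon_ : float             fluctuation coefficient
    score_residual_ : float      mean H (Y - qa*) after targeting
    g1_ : ndarray                truncated propensity estimates
    influence_curve_ : ndarray
    initial_ate_ : float         plug-in ATE of the untargeted SL fit
    result_ : ATEResult
    """

    def __init__(
        self,
        adjustment="correct",
        outcome_learners="default",
        propensity_learners="default",
        v=10,
        lb=0.025,
        max_iter=100,
        tol=1e-8,
        random_state=0,
        treatment_col="A",
        outcome_col="Y",
        estimator_label="TMLE",
    ):
        self.adjustment = adjustment
        self.outcome_learners = outcome_learners
        self.propensity_learners = propensity_learners
        self.v = v
        self.lb = lb
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.treatment_col = treatment_col
        self.outcome_col = outcome_col
        self.estimator_label = estimator_label

    def _terms(self):
        if isinstance(self.adjustment, str):
            return ADJUSTMENTS[self.adjustment]
        return tuple(self.adjustment)

    def fit(self, data: pd.DataFrame, y=None):
        validate_table(data)
        terms = list(self._terms())
        label = self.adjustment if isinstance(self.adjustment, str) else "custom"
        seeds = np.random.SeedSequence(self.random_state).generate_state(3) % (2**31)
        yv = data[self.outcome_col].to_numpy(dtype=float)
        a = data[self.treatment_col].to_numpy(dtype=float)

        # initial outcome regression Q̄(A, W) by super learning
        Xq = data[terms + [self.treatment_col]].to_numpy(dtype=float)
        q_sl = SuperLearner(
            learners=self.outcome_learners,
            task="regression",
            v=self.v,
            random_state=int(seeds[0]),
        )
        q_sl.fit(Xq, yv)
        X1 = Xq.copy()
        X1[:, -1] = 1.0
        X0 = Xq.copy()
        X0[:, -1] = 0.0
        q1 = np.clip(q_sl.predict(X1), _QCLIP, 1 - _QCLIP)
        q0 = np.clip(q_sl.predict(X0), _QCLIP, 1 - _QCLIP)
        qa = np.where(a == 1, q1, q0)

        # propensity and clever covariate
        g = estimate_propensity(
            data,
            terms,
            roster=self.propensity_learners,
            v=self.v,
            lb=self.lb,
            seed=int(seeds[1]),
            treatment_col=self.treatment_col,
        )
        H = clever_covariate(data, g, self.treatment_col)

        fluct, targeted = fluctuate(
            yv, q1, q0, qa, g, H, max_iter=self.max_iter, tol=self.tol
        )
        est = float(np.mean(targeted.q1_star - targeted.q0_star))
        ci = ic_variance(yv, targeted, H, est)

        self.outcome_model_ = q_sl
        self.propensity_fit_ = g
        self.g1_ = g.g1
        self.clever_covariate_ = H.H
        self.epsilon_ = fluct.epsilon
        self.score_residual_ = fluct.score_residual
        self.targeted_ = targeted
        self.initial_ate_ = float(np.mean(q1 - q0))
        self.influence_curve_ = (
            H.H * (yv - targeted.qa_star) + (targeted.q1_star - targeted.q0_star) - est
        )
        self.result_ = ate_tmle(targeted, ci, self.estimator_label, label)
        self.ate_ = est
        self.ci_ = ci
        return self
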