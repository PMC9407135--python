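"""Targeting step: propensity truncation, clever covariate, logistic
fluctuation, influence-curve inference, and double robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from soccertmle.simulate import SimConfig, simulate, true_ate
from soccertmle.tmle import (
    CleverCovariate,
    PropensityFit,
    TargetedOutcome,
    TMLEATE,
    ate_tmle,
    clever_covariate,
    estimate_propensity,
    fluctuate,
    ic_variance,
)


def _frame(a):
    return pd.DataFrame({"A": a})


class TestPropensity:
    def test_randomized_treatment_recovered(self, rng):
        n = 10_000
        d = pd.DataFrame(
            {"W1": rng.integers(1, 10, n), "W2": rng.integers(0, 4, n),
             "W3": rng.integers(0, 2, n), "A": rng.binomial(1, 0.5, n)}
        )
        fit = estimate_propensity(d, ("W1", "W2", "W3"), roster="parametric", v=5)
        assert abs(fit.g1.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_truncation_contract(self, small_data):
        fit = estimate_propensity(
            small_data, ("W1", "W2"), roster=["mean", "glm"], v=5, lb=0.025
        )
        assert fit.g1.min() >= 0.025 and fit.g1.max() <= 0.975

    def test_recovers_known_logit_model(self, default_config):
        """Parametric-logit fit on simulator data matches the structural
        propensities stratum by stratum."""
        d = simulate(default_config, 40_000, seed=21)
        fit = estimate_propensity(d, ("W1", "W2"), roster="parametric", v=5, lb=0.01)
        for (w1, w2), sub in d.groupby(["W1", "W2"]):
            if len(sub) < 200:
                continue
            truth = default_config.propensity(w1, w2)
            se = np.sqrt(truth * (1 - truth) / len(sub))
            est = fit.g1[sub.index.to_numpy()].mean()
            assert abs(est - truth) < 4 * max(se, 0.005)

    def test_constant_treatment_rejected(self):
        d = pd.DataFrame({"W1": [1, 2, 3, 4], "A": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="positivity"):
            estimate_propensity(d, ("W1",), roster="parametric", v=2)

    def test_invalid_truncation_rejected(self, small_data):
        with pytest.raises(ValueError, match="truncation"):
            estimate_propensity(small_data, ("W1",), lb=0.6)


class TestCleverCovariate:
    @pytest.mark.parametrize(
        "a,g1,expected",
        [(1, 0.5, 2.0), (0, 0.75, -4.0), (1, 0.025, 40.0), (0, 0.975, -40.0)],
    )
    def test_formula_values(self, a, g1, expected):
        H = clever_covariate(_frame([a]), PropensityFit(np.array([g1]), lb=0.025))
        assert H.H[0] == pytest.approx(expected, abs=1e-12)

    def test_sign_structure_and_bound(self, small_data):
        g = estimate_propensity(small_data, ("W1", "W2"), roster="parametric", v=5)
        H = clever_covariate(small_data, g)
        a = small_data.A.to_numpy()
        assert np.all(H.H[a == 1] > 0) and np.all(H.H[a == 0] < 0)
        assert np.max(np.abs(H.H)) <= 1 / g.lb + 1e-9


def _hand_problem():
    """Eight-row fluctuation problem with analytically awkward inputs."""
    y = np.array([0.1, 0.9, 0.3, 0.7, 0.2, 0.8, 0.55, 0.45])
    a = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    g1 = np.array([0.3, 0.4, 0.5, 0.6, 0.35, 0.45, 0.55, 0.65])
    q1 = np.array([0.3, 0.6, 0.4, 0.5, 0.35, 0.65, 0.5, 0.4])
    q0 = np.array([0.2, 0.5, 0.3, 0.6, 0.3, 0.55, 0.45, 0.5])
    qa = np.where(a == 1, q1, q0)
    g = PropensityFit(g1, lb=0.025)
    H = clever_covariate(pd.DataFrame({"A": a}), g)
    return y, a, g, H, q1, q0, qa


class TestFluctuation:
    def test_epsilon_matches_1d_likelihood_search(self):
        """Newton solution agrees with direct 1-D maximisation of the
        Bernoulli quasi-log-likelihood to 1e-5."""
        y, a, g, H, q1, q0, qa = _hand_problem()
        fluct, _ = fluctuate(y, q1, q0, qa, g, H)

        off = logit(qa)

        def negloglik(eps):
            p = np.clip(expit(off + eps * H.H), 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        grid = minimize_scalar(negloglik, bounds=(-5, 5), method="bounded",
                               options={"xatol": 1e-10})
        assert fluct.epsilon == pytest.approx(grid.x, abs=1e-5)

    def test_score_equation_solved(self):
        y, a, g, H, q1, q0, qa = _hand_problem()
        fluct, targeted = fluctuate(y, q1, q0, qa, g, H)
        assert abs(np.mean(H.H * (y - targeted.qa_star))) <= 1e-6
        assert abs(fluct.score_residual) <= 1e-6

    def test_fixed_point_when_score_already_zero(self, rng):
        """If the initial fit already solves the score equation, epsilon is
        (numerically) zero and the targeted predictions are unchanged."""
        n = 400
        a = rng.binomial(1, 0.5, n)
        y = rng.uniform(0.2, 0.8, n)
        qa = y.copy()  # perfect fit: residual is identically zero
        q1 = np.where(a == 1, y, 0.5)
        q0 = np.where(a == 0, y, 0.5)
        g = PropensityFit(np.full(n, 0.5), lb=0.025)
        H = clever_covariate(pd.DataFrame({"A": a}), g)
        fluct, targeted = fluctuate(y, q1, q0, qa, g, H)
        assert abs(fluct.epsilon) < 1e-6
        np.testing.assert_allclose(targeted.q1_star, q1, atol=1e-5)
        np.testing.assert_allclose(targeted.q0_star, q0, atol=1e-5)

    def test_targeted_predictions_strictly_inside_unit_interval(self, rng):
        n = 200
        a = rng.binomial(1, 0.3, n)
        y = rng.uniform(0, 1, n)  # includes exact 0/1 neighbourhoods
        q1 = rng.uniform(0, 1, n)
        q0 = rng.uniform(0, 1, n)
        qa = np.where(a == 1, q1, q0)
        g = PropensityFit(np.clip(rng.uniform(0.05, 0.95, n), 0.025, 0.975), lb=0.025)
        H = clever_covariate(pd.DataFrame({"A": a}), g)
        _, targeted = fluctuate(y, q1, q0, qa, g, H)
        for arr in (targeted.q1_star, targeted.q0_star, targeted.qa_star):
            assert np.all(arr > 0) and np.all(arr < 1)

    def test_monotone_targeting_in_epsilon(self):
        """Larger epsilon moves every q1* up and every q0* down (the sign
        structure of the clever covariate)."""
        y, a, g, H, q1, q0, qa = _hand_problem()
        up1 = expit(logit(q1) + 0.5 / g.g1)
        up0 = expit(logit(q0) - 0.5 / g.g0)
        lo1 = expit(logit(q1) + 0.1 / g.g1)
        lo0 = expit(logit(q0) - 0.1 / g.g0)
        assert np.all(up1 > lo1) and np.all(up0 < lo0)


class TestInference:
    def test_null_fluctuation_identity(self):
        y, a, g, H, q1, q0, qa = _hand_problem()
        targeted = TargetedOutcome(q1_star=q1, q0_star=q0, qa_star=qa)
        res = ate_tmle(targeted)
        assert res.estimate == pytest.approx(np.mean(q1 - q0), abs=1e-15)

    def test_constant_influence_gives_zero_width(self):
        n = 50
        q1 = np.full(n, 0.6)
        q0 = np.full(n, 0.4)
        y = np.full(n, 0.5)
        qa = np.full(n, 0.5)
        targeted = TargetedOutcome(q1, q0, qa)
        H = CleverCovariate(np.full(n, 2.0))
        lo, hi = ic_variance(y, targeted, H, 0.2)
        assert lo == pytest.approx(0.2, abs=1e-12)
        assert hi == pytest.approx(0.2, abs=1e-12)

    def test_insufficient_data_rejected(self):
        t = TargetedOutcome(np.array([0.5]), np.array([0.4]), np.array([0.5]))
        with pytest.raises(ValueError):
            ic_variance(np.array([0.5]), t, CleverCovariate(np.array([2.0])), 0.1)

    def test_ci_width_shrinks_at_root_n_rate(self, default_config):
        widths = {}
        for n in (500, 2000, 8000):
            d = simulate(default_config, n, seed=31)
            est = TMLEATE(
                "correct", outcome_learners="fast", propensity_learners="parametric",
                v=5, random_state=5,
            ).fit(d)
            widths[n] = est.ci_[1] - est.ci_[0]
        assert widths[500] / widths[2000] == pytest.approx(2.0, rel=0.2)
        assert widths[2000] / widths[8000] == pytest.approx(2.0, rel=0.2)


class TestTMLEEstimator:
    def test_score_residual_and_bounds_on_simulator_data(self, small_data):
        est = TMLEATE(
            "correct", outcome_learners="fast", propensity_learners="parametric",
            v=5, random_state=0,
        ).fit(small_data)
        assert abs(est.score_residual_) <= 1e-6
        assert est.ci_[0] <= est.ate_ <= est.ci_[1]
        assert np.all((est.g1_ >= est.lb) & (est.g1_ <= 1 - est.lb))

    def test_row_permutation_invariance(self, small_data):
        base = TMLEATE(
            "correct", outcome_learners=["glm"], propensity_learners="parametric",
            v=5, random_state=0,
        ).fit(small_data)
        shuffled = small_data.sample(frac=1, random_state=3).reset_index(drop=True)
        shuffled.attrs = dict(small_data.attrs)
        perm = TMLEATE(
            "correct", outcome_learners=["glm"], propensity_learners="parametric",
            v=5, random_state=0,
        ).fit(shuffled)
        assert perm.ate_ == pytest.approx(base.ate_, abs=1e-9)

    def test_double_robustness_under_misspecified_outcome_model(self, default_config):
        """Outcome roster restricted to the misspecified main-effects linear
        learner, propensity correctly specified: the TMLE replicate mean
        stays within Monte-Carlo error of the truth while the plain GLM
        plug-in is shifted away from it."""
        truth = true_ate(default_config, 400_000, seed=99)
        reps = 60
        n = 1500
        tmle_raw, glm_raw = [], []
        for r in range(reps):
            d = simulate(default_config, n, seed=10_000 + r)
            width = d.attrs["y_max"] - d.attrs["y_min"]
            est = TMLEATE(
                "correct", outcome_learners=["glm"], propensity_learners="parametric",
                v=5, random_state=r,
            ).fit(d)
            tmle_raw.append(est.ate_ * width)
            glm_raw.append(est.initial_ate_ * width)
        tmle_raw = np.asarray(tmle_raw)
        glm_raw = np.asarray(glm_raw)
        mc_se = tmle_raw.std(ddof=1) / np.sqrt(reps)
        assert abs(tmle_raw.mean() - truth.value_raw) < 3 * mc_se
        glm_se = glm_raw.std(ddof=1) / np.sqrt(reps)
        assert abs(glm_raw.mean() - truth.value_raw) > 3 * glm_se
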