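"""Structural simulator for the substitution causal model.

The data-generating process follows the causal graph of the substitution
problem: per five-minute period of a second half we observe
``O = (W1, W2, W3, A, Y)`` where

* ``W1`` — period index within the half (discrete uniform on ``1..n_periods``),
* ``W2`` — number of substitutes already on the pitch, drawn binomially with
  a success probability that grows with ``W1`` (substitutions accumulate),
* ``W3`` — indicator of a substitution *during* the current period
  (causes a dead-ball moment, lowering team distance); depends on ``W1`` only,
* ``A``  — indicator of a substitution in the *previous* period, the
  treatment; its propensity rises with ``W1`` and falls with ``W2``,
* ``Y``  — total team distance in the period, generated as a structural
  mean plus Gaussian noise and min-max normalised to ``[0, 1]``.

All exogenous noise (the ``U`` node of the graph) lives in the RNG draws, so
counterfactual outcomes ``Y(a)`` are available by re-evaluating the
structural mean with ``A`` forced while sharing the same noise realisation.

Crucially for the misspecification study, ``W3`` is drawn independently of
``A`` given ``W1``: it predicts the outcome but does not confound the
treatment, so dropping it from an adjustment set leaves the ATE identified.
The treatment effect is heterogeneous in ``W2`` (``A×W2`` interaction),
which makes the main-effects linear model's ``A`` coefficient differ from
the ATE even when every confounder is included.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "SimConfig",
    "TrueATE",
    "COLUMNS",
    "simulate",
    "draw_counterfactuals",
    "true_ate",
    "validate_table",
    "minmax_normalize",
]

#: canonical column order of an observation table
COLUMNS = ["W1", "W2", "W3", "A", "Y", "Y_raw"]


@dataclass
class SimConfig:
    """Structural-equation coefficients and noise scales of the simulator.

    The default values are the package's calibrated reference condition:
    treatment probability increases over the half and decreases with the
    number of substitutes already present; team distance declines
    quadratically over the half; a current-period substitution costs
    distance; and the benefit of a fresh substitute shrinks as more
    substitutes are already on the pitch (negative ``A×W2`` interaction,
    the source of the main-effects-GLM bias).

    Parameters
    ----------
    n_periods : int
        Number of five-minute periods in the half.
    max_subs : int
        Cap on the number of substitutes present (binomial size for W2).
    coef_A : (a0, a1, a2)
        Treatment logit ``a0 + a1*W1 - a2*W2`` (note the minus on ``a2``).
    coef_W2 : (b0, b1)
        Per-slot success logit ``b0 + b1*W1`` of ``W2 ~ Bin(max_subs, .)``.
    coef_W3 : (c0, c1)
        Current-period substitution logit ``c0 + c1*W1``.
    coef_Y : 7-tuple
        ``(intercept, W1, W1^2, W2, W3, A, A*W2)`` of the structural mean
        of the raw outcome, in meters.
    noise_sd : float
        Standard deviation of the additive Gaussian outcome noise (meters).
    seed : int
        Default RNG seed used when an operation is not given its own.
    """

    n_periods: int = 9
    max_subs: int = 3
    coef_A: tuple = (-0.6, 0.32, 1.05)
    coef_W2: tuple = (-1.2, 0.22)
    coef_W3: tuple = (-2.5, 0.25)
    coef_Y: tuple = (5400.0, -126.0, 7.0, 50.0, -120.0, 212.0, -103.0)
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.max_subs < 1:
            raise ValueError("max_subs must be >= 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")

    # -- structural equations -------------------------------------------------

    def propensity(self, w1, w2):
        """True P(A=1 | W1, W2) implied by ``coef_A``."""
        a0, a1, a2 = self.coef_A
        return expit(a0 + a1 * np.asarray(w1) - a2 * np.asarray(w2))

    def structural_mean(self, w1, w2, w3, a):
        """E[Y_raw | W1, W2, W3, A] in meters."""
        y0, y1, y2, y3, y4, y5, y6 = self.coef_Y
        w1 = np.asarray(w1, dtype=float)
        w2 = np.asarray(w2, dtype=float)
        w3 = np.asarray(w3, dtype=float)
        a = np.asarray(a, dtype=float)
        return y0 + y1 * w1 + y2 * w1**2 + y3 * w2 + y4 * w3 + y5 * a + y6 * a * w2

    def positivity_by_construction(self):
        """Enumerate all attainable (W1, W2) strata; True if every implied
        propensity is strictly inside (0, 1)."""
        w1 = np.repeat(np.arange(1, self.n_periods + 1), self.max_subs + 1)
        w2 = np.tile(np.arange(self.max_subs + 1), self.n_periods)
        g = self.propensity(w1, w2)
        return bool(np.all((g > 0.0) & (g < 1.0)))

    # -- serialisation --------------------------------------------------------

    def to_yaml(self, path=None):
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        """Load from a YAML path, file object, or string."""
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(io.StringIO(str(source)).read())
        for k in ("coef_A", "coef_W2", "coef_W3", "coef_Y"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TrueATE:
    """Monte-Carlo ground-truth ATE of the simulator.

    ``value`` is on the normalised-outcome scale (raw contrast divided by the
    min-max range of the factual Monte-Carlo sample); ``value_raw`` is the
    same contrast in meters; ``mc_se`` is the Monte-Carlo standard error of
    ``value``.
    """

    value: float
    value_raw: float
    mc_draws: int
    mc_se: float
    y_range: float


def minmax_normalize(y):
    """Min-max normalise an array; returns (normalised, min, max).

    A constant (or empty) input has no defined min-max scale; it is mapped to
    0.5 with the degenerate bounds recorded as-is.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        return y.copy(), np.nan, np.nan
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi > lo:
        return (y - lo) / (hi - lo), lo, hi
    return np.full_like(y, 0.5), lo, hi


def denormalize(values, y_min, y_max):
    """Back-transform normalised outcome-scale quantities to meters.

    For level quantities use ``values * (y_max - y_min) + y_min``; for
    contrasts (an ATE, a CI half-width) the offset cancels, which is what
    this helper computes: ``values * (y_max - y_min)``.
    """
    return np.asarray(values, dtype=float) * (y_max - y_min)


def draw_counterfactuals(config: SimConfig, n: int, seed=None) -> pd.DataFrame:
    """Draw n units with both potential outcomes evaluated on shared noise.

    Returns a frame with columns W1, W2, W3, A, Y_raw, Y1_raw, Y0_raw where
    ``Y_raw`` is the factual outcome, i.e. ``Y1_raw`` where A=1 and
    ``Y0_raw`` where A=0 (counterfactual consistency holds exactly).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w1 = rng.integers(1, config.n_periods + 1, size=n)
    b0, b1 = config.coef_W2
    w2 = rng.binomial(config.max_subs, expit(b0 + b1 * w1))
    c0, c1 = config.coef_W3
    w3 = rng.binomial(1, expit(c0 + c1 * w1))
    a = rng.binomial(1, config.propensity(w1, w2))
    eps = rng.normal(0.0, config.noise_sd, size=n)
    y1 = config.structural_mean(w1, w2, w3, 1) + eps
    y0 = config.structural_mean(w1, w2, w3, 0) + eps
    y = np.where(a == 1, y1, y0)
    return pd.DataFrame(
        {"W1": w1, "W2": w2, "W3": w3, "A": a, "Y_raw": y, "Y1_raw": y1, "Y0_raw": y0}
    )


def simulate(config: SimConfig, n: int, seed=None) -> pd.DataFrame:
    """Generate an observation table of n i.i.d. team-period rows.

    The returned frame has columns ``W1, W2, W3, A, Y, Y_raw`` with ``Y``
    min-max normalised over the dataset; the normalisation bounds are stored
    in ``df.attrs["y_min"]`` / ``df.attrs["y_max"]``.  Identical
    ``(config, n, seed)`` reproduce the table bit-for-bit.
    """
    cf = draw_counterfactuals(config, n, seed)
    y_norm, lo, hi = minmax_normalize(cf["Y_raw"].to_numpy())
    out = pd.DataFrame(
        {
            "W1": cf["W1"].astype(np.int64),
            "W2": cf["W2"].astype(np.int64),
            "W3": cf["W3"].astype(np.int64),
            "A": cf["A"].astype(np.int64),
            "Y": y_norm,
            "Y_raw": cf["Y_raw"],
        }
    )
    out.attrs["y_min"] = lo
    out.attrs["y_max"] = hi
    return out


def true_ate(config: SimConfig, mc_draws: int = 1_000_000, seed=None) -> TrueATE:
    """Ground-truth ATE by Monte-Carlo counterfactual contrast.

    Evaluates both potential outcomes per unit on shared noise, averages
    ``Y(1) - Y(0)`` (in meters) and divides by the min-max range of the
    factual sample to express the truth on the normalised-outcome scale,
    mirroring the dataset-level normalisation convention of ``simulate``.
    """
    if mc_draws < 1:
        raise ValueError("mc_draws must be >= 1")
    cf = draw_counterfactuals(config, mc_draws, seed)
    diff = (cf["Y1_raw"] - cf["Y0_raw"]).to_numpy()
    _, lo, hi = minmax_normalize(cf["Y_raw"].to_numpy())
    rng_width = hi - lo if hi > lo else 1.0
    value_raw = float(np.mean(diff))
    se_raw = float(np.std(diff, ddof=1) / np.sqrt(mc_draws)) if mc_draws > 1 else 0.0
    return TrueATE(
        value=value_raw / rng_width,
        value_raw=value_raw,
        mc_draws=mc_draws,
        mc_se=se_raw / rng_width,
        y_range=rng_width,
    )


def validate_table(data: pd.DataFrame, require_y_raw: bool = False) -> pd.DataFrame:
    """Check observation-table invariants; returns the frame unchanged.

    Raises ``ValueError`` naming the violated contract: missing columns,
    missing values, non-binary A/W3, or Y outside [0, 1].
    """
    required = ["W1", "W2", "W3", "A", "Y"] + (["Y_raw"] if require_y_raw else [])
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"observation table is missing columns {missing}")
    if len(data) == 0:
        return data
    sub = data[required]
    if sub.isna().any().any():
        bad = sub.isna().any()
        raise ValueError(f"missing values in columns {list(bad.index[bad])}")
    for col in ("A", "W3"):
        vals = set(np.unique(data[col].to_numpy()))
        if not vals <= {0, 1}:
            rows = data.index[~data[col].isin([0, 1])].tolist()[:10]
            raise ValueError(f"{col} must be binary; offending rows: {rows}")
    y = data["Y"].to_numpy(dtype=float)
    if y.min() < -1e-12 or y.max() > 1 + 1e-12:
        raise ValueError("Y must lie in [0, 1]; re-normalise the outcome")
    return data
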