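"""Experiment runners: the simulation/misspecification bias study, the
observed-data analysis, and the positivity diagnostic.

The bias study repeatedly simulates datasets, runs each requested estimator
(GLM g-computation, TMLE with the default roster, TMLEH with the handpicked
roster) under the "correct" adjustment {W1, W2, W3} and the "misspecified"
adjustment that drops W3, and aggregates the estimates against the
simulator's Monte-Carlo ground truth.

Because every simulated dataset carries its own min-max normalisation whose
bounds fluctuate with the sample's noise extremes, estimates are compared
with the truth on the raw (meters) scale — each replicate's estimate is
back-transformed with that replicate's stored bounds — and then expressed
on the normalised scale of the ground-truth sample for reporting, so that
the displayed magnitudes line up with the truth value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .gcomp import ADJUSTMENTS, GComputationATE
from .simulate import SimConfig, denormalize, simulate, true_ate, validate_table
from .tmle import TMLEATE

__all__ = [
    "StudyConfig",
    "run_simulation_study",
    "run_observed_analysis",
    "positivity_check",
    "render_bias_table",
    "render_observed_report",
    "plot_ate_chart",
]

#: estimator label -> (outcome roster, propensity roster) presets
DEFAULT_ROSTERS = {
    "TMLE": ("default", "default"),
    "TMLEH": ("handpicked", "handpicked"),
}


@dataclass
class StudyConfig:
    """Settings of the replicated simulation study."""

    replications: int = 200
    n_per_replicate: int = 5000
    estimators: tuple = ("GLM", "TMLE", "TMLEH")
    adjustments: tuple = ("correct", "misspecified")
    sim: SimConfig = field(default_factory=SimConfig)
    master_seed: int = 0
    v: int = 10
    lb: float = 0.025
    rosters: dict = field(default_factory=lambda: dict(DEFAULT_ROSTERS))
    true_ate_draws: int = 1_000_000

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not self.adjustments:
            raise ValueError("at least one adjustment set is required")

    def to_yaml(self, path=None):
        d = dataclasses.asdict(self)
        d["sim"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d["sim"].items()
        }
        d["estimators"] = list(d["estimators"])
        d["adjustments"] = list(d["adjustments"])
        d["rosters"] = {k: list(v) for k, v in d["rosters"].items()}
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(str(source))
        if "sim" in d and not isinstance(d["sim"], SimConfig):
            for k in ("coef_A", "coef_W2", "coef_W3", "coef_Y"):
                if k in d["sim"]:
                    d["sim"][k] = tuple(d["sim"][k])
            d["sim"] = SimConfig(**d["sim"])
        for k in ("estimators", "adjustments"):
            if k in d:
                d[k] = tuple(d[k])
        if "rosters" in d:
            d["rosters"] = {k: tuple(v) for k, v in d["rosters"].items()}
        return cls(**d)


def _build_estimator(label, adjustment, cfg_rosters, v, lb, seed):
    if label == "GLM":
        return GComputationATE(adjustment=adjustment)
    rosters = cfg_rosters.get(label, DEFAULT_ROSTERS.get(label))
    if rosters is None:
        raise KeyError(f"unknown estimator label {label!r}")
    if isinstance(rosters, str):
        rosters = (rosters, rosters)
    return TMLEATE(
        adjustment=adjustment,
        outcome_learners=rosters[0],
        propensity_learners=rosters[1],
        v=v,
        lb=lb,
        random_state=seed,
        estimator_label=label,
    )


def run_simulation_study(cfg: StudyConfig) -> pd.DataFrame:
    """Replicated bias study; returns the bias table.

    One row per (estimator, adjustment) with the mean ATE, mean 95% CI,
    bias against the simulator ground truth, bias%, and the Monte-Carlo SE
    of the mean ATE, all on the normalised scale of the ground-truth
    sample.  Extra context rides in ``table.attrs``:
    ``true_ate`` / ``true_ate_raw`` / ``y_range`` and the per-replicate
    long-format ``replicates`` frame.  Replicates where an estimator fails
    are excluded for that cell and counted in ``n_excluded``.
    """
    ss = np.random.SeedSequence(cfg.master_seed)
    state = ss.generate_state(2 * cfg.replications + 1) % (2**31)
    truth = true_ate(cfg.sim, cfg.true_ate_draws, seed=int(state[-1]))

    records = []
    for r in range(cfg.replications):
        data = simulate(cfg.sim, cfg.n_per_replicate, seed=int(state[2 * r]))
        width = data.attrs["y_max"] - data.attrs["y_min"]
        for est_label in cfg.estimators:
            for adj in cfg.adjustments:
                est = _build_estimator(
                    est_label, adj, cfg.rosters, cfg.v, cfg.lb, int(state[2 * r + 1])
                )
                try:
                    est.fit(data)
                    ok = True
                except Exception:
                    ok = False
                records.append(
                    {
                        "replicate": r,
                        "estimator": est_label,
                        "adjustment": adj,
                        "ate_raw": float(denormalize(est.ate_, 0, width)) if ok else np.nan,
                        "ci_low_raw": float(denormalize(est.ci_[0], 0, width)) if ok else np.nan,
                        "ci_high_raw": float(denormalize(est.ci_[1], 0, width)) if ok else np.nan,
                        "failed": not ok,
                    }
                )
    reps = pd.DataFrame.from_records(records)

    rows = []
    scale = truth.y_range
    for est_label in cfg.estimators:
        for adj in cfg.adjustments:
            cell = reps[(reps.estimator == est_label) & (reps.adjustment == adj)]
            good = cell[~cell.failed]
            mean_raw = good.ate_raw.mean()
            mc_se_raw = (
                good.ate_raw.std(ddof=1) / np.sqrt(len(good)) if len(good) > 1 else 0.0
            )
            rows.append(
                {
                    "estimator": est_label,
                    "adjustment": adj,
                    "mean_ate": mean_raw / scale,
                    "ci_low": good.ci_low_raw.mean() / scale,
                    "ci_high": good.ci_high_raw.mean() / scale,
                    "bias": (mean_raw - truth.value_raw) / scale,
                    "bias_pct": (
                        100.0 * (mean_raw - truth.value_raw) / truth.value_raw
                        if truth.value_raw != 0
                        else np.nan
                    ),
                    "mc_se": mc_se_raw / scale,
                    "n_replicates": int(len(good)),
                    "n_excluded": int(cell.failed.sum()),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["true_ate"] = truth.value
    table.attrs["true_ate_raw"] = truth.value_raw
    table.attrs["y_range"] = truth.y_range
    table.attrs["replicates"] = reps
    return table


def run_observed_analysis(
    data: pd.DataFrame,
    estimators=("GLM", "TMLE", "TMLEH"),
    rosters=None,
    v=10,
    lb=0.025,
    seed=0,
) -> pd.DataFrame:
    """ATE analysis of an observed per-period table.

    Runs every requested estimator under the correct ({W1, W2, W3}) and
    misspecified ({W1, W2}) adjustment sets and appends, per estimator, the
    between-adjustment difference and difference-%.  Returns a tidy frame
    with columns estimator / adjustment / ate / ci_low / ci_high plus
    difference rows labelled adjustment="difference" and "difference_pct".
    """
    validate_table(data)
    rosters = dict(DEFAULT_ROSTERS, **(rosters or {}))
    seeds = np.random.SeedSequence(seed).generate_state(len(estimators)) % (2**31)
    rows = []
    for k, est_label in enumerate(estimators):
        by_adj = {}
        for adj in ("correct", "misspecified"):
            est = _build_estimator(est_label, adj, rosters, v, lb, int(seeds[k]))
            est.fit(data)
            by_adj[adj] = est.ate_
            rows.append(
                {
                    "estimator": est_label,
                    "adjustment": adj,
                    "ate": est.ate_,
                    "ci_low": est.ci_[0],
                    "ci_high": est.ci_[1],
                }
            )
        diff = by_adj["misspecified"] - by_adj["correct"]
        rows.append(
            {
                "estimator": est_label,
                "adjustment": "difference",
                "ate": diff,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
        rows.append(
            {
                "estimator": est_label,
                "adjustment": "difference_pct",
                "ate": 100.0 * diff / by_adj["correct"]
                if by_adj["correct"] != 0
                else np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["n"] = int(len(data))
    return report


def positivity_check(data: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate treatment within (W1, W2) strata; flag empty arms.

    W3 is collapsed to keep cells well filled; a flagged stratum has zero
    treated or zero control rows, i.e. an empirical positivity violation.
    """
    if len(data) == 0:
        raise ValueError("positivity check needs a non-empty table")
    tab = (
        data.assign(treated=data["A"] == 1)
        .groupby(["W1", "W2"], as_index=False)
        .agg(n_treated=("treated", "sum"), n_total=("treated", "size"))
    )
    tab["n_treated"] = tab["n_treated"].astype(int)
    tab["n_control"] = tab["n_total"] - tab["n_treated"]
    tab["flagged"] = (tab.n_treated == 0) | (tab.n_control == 0)
    tab = tab[["W1", "W2", "n_treated", "n_control", "flagged"]]
    assert int(tab.n_treated.sum() + tab.n_control.sum()) == len(data)
    return tab


# ---------------------------------------------------------------------------
# rendering


def render_bias_table(table: pd.DataFrame) -> str:
    """Human-readable text rendering of a bias table."""
    lines = [f"True ATE: {table.attrs.get('true_ate', float('nan')):.4f}", ""]
    disp = table.copy()
    for c in ("mean_ate", "ci_low", "ci_high", "bias", "mc_se"):
        disp[c] = disp[c].map(lambda x: f"{x:.4f}")
    disp["bias_pct"] = table["bias_pct"].map(lambda x: f"{x:.2f}")
    lines.append(disp.to_string(index=False))
    return "\n".join(lines) + "\n"


def render_observed_report(report: pd.DataFrame) -> str:
    lines = [f"Observed dataset analysis (n = {report.attrs.get('n', '?')})", ""]
    disp = report.copy()
    for c in ("ate", "ci_low", "ci_high"):
        disp[c] = disp[c].map(lambda x: "" if pd.isna(x) else f"{x:.4f}")
    lines.append(disp.to_string(index=False))
    return "\n".join(lines) + "\n"


def plot_ate_chart(table: pd.DataFrame, path, true_ate=None):
    """Point-and-CI chart of per-estimator ATEs (bias study or observed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "mean_ate" in table.columns:
        sub = table
        labels = [f"{r.estimator}\n{r.adjustment}" for r in sub.itertuples()]
        y = sub["mean_ate"].to_numpy()
        lo, hi = sub["ci_low"].to_numpy(), sub["ci_high"].to_numpy()
        if true_ate is None:
            true_ate = table.attrs.get("true_ate")
    else:
        sub = table[table.adjustment.isin(["correct", "misspecified"])]
        labels = [f"{r.estimator}\n{r.adjustment}" for r in sub.itertuples()]
        y = sub["ate"].to_numpy()
        lo, hi = sub["ci_low"].to_numpy(), sub["ci_high"].to_numpy()
    x = np.arange(len(y))
    fig, ax = plt.subplots(figsize=(1.2 * len(y) + 2, 4))
    ax.errorbar(x, y, yerr=[y - lo, hi - y], fmt="o", capsize=4)
    if true_ate is not None:
        ax.axhline(true_ate, ls="--", color="gray", label="true ATE")
        ax.legend()
    ax.set_xticks(x, labels, fontsize=8)
    ax.set_ylabel("ATE (normalised outcome)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
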