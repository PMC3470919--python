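"""Group-level inference over per-subject ROI accuracies and behavior.

Accuracies arrive as a subjects x ROI table (optionally per hemisphere;
hemispheres are averaged first, mirroring analyses collapsed across
hemisphere). Above-chance decoding is assessed with a one-sample two-sided
t-test against the two-class chance level of 0.5; regions are compared
with a one-way repeated-measures ANOVA over the ROI factor with paired
t-test follow-ups (uncorrected and Holm-adjusted p-values).

Behavioral summaries reproduce the psychometric read-outs: per-morph-level
choice/RT/confidence curves and a maximum-likelihood logistic fit with
lapse rate, exposed statsmodels-style as
``PsychometricModel.from_dataframe(table).fit()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .synth import BehaviorModel, psychometric_probability

__all__ = [
    "above_chance_test",
    "collapse_hemispheres",
    "rm_anova_regions",
    "AnovaResult",
    "behavior_summary",
    "BehaviorSummary",
    "PsychometricModel",
    "PsychometricResults",
]

CHANCE_TWO_CLASS = 0.5
#: |slope| at which a psychometric fit is reported as at ceiling
SLOPE_CEILING = 10.0


def above_chance_test(accuracies, chance: float = CHANCE_TWO_CLASS):
    """One-sample two-sided t-test of subject accuracies against chance.

    Returns ``(t, p)``. With zero variance exactly at chance the test is
    undefined; by convention t=0, p=1 (no evidence either way).
    """
    a = np.asarray(accuracies, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 subjects")
    if np.allclose(a.std(ddof=1), 0.0):
        if np.isclose(a.mean(), chance):
            warnings.warn("zero variance at chance; returning t=0, p=1")
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - chance), 0.0
    t, p = stats.ttest_1samp(a, popmean=chance)
    return float(t), float(p)


def collapse_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Average 'ROI-L'/'ROI-R' accuracy columns into per-ROI columns."""
    roots = sorted({c.rsplit("-", 1)[0] for c in table.columns
                    if c.endswith(("-L", "-R"))})
    if not roots:
        return table.copy()
    out = pd.DataFrame(index=table.index)
    for r in roots:
        pair = [c for c in (f"{r}-L", f"{r}-R") if c in table.columns]
        out[r] = table[pair].mean(axis=1)
    return out


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA over the region factor."""

    F: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"RM-ANOVA (region): F({self.df_num}, {self.df_den}) = "
                 f"{self.F:.4f}, p = {self.p_value:.4g}"]
        if self.pairwise is not None:
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def rm_anova_regions(table: pd.DataFrame, pairwise: bool = True) -> AnovaResult:
    """Repeated-measures ANOVA of subjects x regions accuracies.

    ``table`` must be complete (one accuracy per subject per region).
    Follow-up paired t-tests report uncorrected and Holm-adjusted p-values.
    """
    if table.isna().any().any():
        raise ValueError("missing cells in the subjects x regions table")
    regions = list(table.columns)
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="region", value_name="accuracy")
    if np.allclose(table.to_numpy().std(axis=0).sum(), 0) and \
       np.allclose(np.ptp(table.to_numpy(), axis=1), 0):
        # identical columns and no residual variance: F = 0 by definition
        n, k = table.shape
        return AnovaResult(0.0, k - 1, (n - 1) * (k - 1), 1.0,
                           _pairwise_tests(table) if pairwise else None)
    res = AnovaRM(long, depvar="accuracy", subject="subject",
                  within=["region"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult(
        F=float(row["F Value"]), df_num=int(row["Num DF"]),
        df_den=int(row["Den DF"]), p_value=float(row["Pr > F"]),
        pairwise=_pairwise_tests(table) if pairwise else None)


def _pairwise_tests(table: pd.DataFrame) -> pd.DataFrame:
    regions = list(table.columns)
    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            a, b = table[regions[i]], table[regions[j]]
            if np.allclose(a - b, (a - b).iloc[0]):
                # constant difference: degenerate paired test
                t, p = (0.0, 1.0) if np.allclose(a, b) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_rel(a, b)
            rows.append({"pair": f"{regions[i]} vs {regions[j]}",
                         "t": float(t), "p_uncorrected": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_uncorrected"], method="holm")[1]
    return out


@dataclass
class PsychometricResults:
    """MLE logistic psychometric fit (slope, bias, lapse)."""

    slope: float
    bias: float
    lapse: float
    llf: float
    n_trials: int
    converged: bool
    at_ceiling: bool
    model: "PsychometricModel" = field(repr=False, default=None)

    @property
    def params(self) -> pd.Series:
        return pd.Series({"slope": self.slope, "bias": self.bias,
                          "lapse": self.lapse})

    def predict(self, morph_pct_A) -> np.ndarray:
        bm = BehaviorModel(slope=self.slope, bias=self.bias, lapse=self.lapse)
        return psychometric_probability(morph_pct_A, bm)

    def summary(self) -> str:
        ceil = "  [slope at ceiling: choices are separable]" if self.at_ceiling else ""
        return (
            "Psychometric fit (logistic with lapse)\n"
            f"  slope = {self.slope:.4f} per %A{ceil}\n"
            f"  bias (PSE) = {self.bias:.2f} %A\n"
            f"  lapse = {self.lapse:.4f}\n"
            f"  log-likelihood = {self.llf:.2f}  (n = {self.n_trials} trials)"
        )


class PsychometricModel:
    """Bernoulli MLE of P(choose A | morph level) with lapse rate.

    P(x) = lapse/2 + (1 - lapse) * logistic(slope * (x - bias)).
    """

    def __init__(self, morph_pct_A, chose_a):
        self.x = np.asarray(morph_pct_A, dtype=float)
        self.k = np.asarray(chose_a, dtype=float)
        if self.x.shape != self.k.shape or self.x.ndim != 1:
            raise ValueError("morph levels and choices must be equal-length 1-D")
        if not np.all(np.isin(self.k, (0.0, 1.0))):
            raise ValueError("chose_a must be binary")

    @classmethod
    def from_dataframe(cls, trial_table: pd.DataFrame) -> "PsychometricModel":
        return cls(trial_table["condition_pct_A"].to_numpy(),
                   (trial_table["choice"].to_numpy() == "A").astype(float))

    def _nll(self, theta) -> float:
        slope, bias, lapse = theta
        bm = BehaviorModel(slope=slope, bias=bias, lapse=min(lapse, 0.499))
        p = np.clip(psychometric_probability(self.x, bm), 1e-12, 1 - 1e-12)
        return -float(np.sum(self.k * np.log(p) + (1 - self.k) * np.log1p(-p)))

    def fit(self) -> PsychometricResults:
        starts = [(0.1, 50.0, 0.02), (0.5, 50.0, 0.05), (1.0, 50.0, 0.01),
                  (-0.1, 50.0, 0.02)]
        bounds = [(-SLOPE_CEILING, SLOPE_CEILING), (0.0, 100.0), (0.0, 0.45)]
        best = None
        for s0 in starts:
            r = optimize.minimize(self._nll, x0=s0, bounds=bounds,
                                  method="L-BFGS-B")
            if best is None or r.fun < best.fun:
                best = r
        slope, bias, lapse = best.x
        return PsychometricResults(
            slope=float(slope), bias=float(bias), lapse=float(lapse),
            llf=-float(best.fun), n_trials=len(self.x),
            converged=bool(best.success),
            at_ceiling=bool(abs(slope) >= 0.99 * SLOPE_CEILING),
            model=self)


@dataclass
class BehaviorSummary:
    """Per-morph-level behavior curves plus the psychometric fit."""

    per_level: pd.DataFrame
    fit: PsychometricResults

    def summary(self) -> str:
        return self.per_level.to_string(index=False) + "\n\n" + self.fit.summary()


def behavior_summary(trial_table: pd.DataFrame) -> BehaviorSummary:
    """Accuracy/RT/confidence per morph level and the psychometric fit.

    'Accuracy' is the proportion of choices matching the majority scene of
    the stimulus; at the fully ambiguous 50% level it is undefined and
    reported as NaN. Levels with zero trials are simply absent (a warning
    is emitted if the table is empty at any declared level grouping —
    grouping is data-driven here).
    """
    t = trial_table.copy()
    cond = t["condition_pct_A"].astype(float)
    majority = np.where(cond > 50, "A", np.where(cond < 50, "B", ""))
    t["p_choose_A"] = (t["choice"] == "A").astype(float)
    t["accuracy"] = np.where(majority == "", np.nan,
                             (t["choice"] == majority).astype(float))
    t["level_pct_A"] = cond
    per_level = (t.groupby("level_pct_A", as_index=False)
                 .agg(n_trials=("choice", "size"),
                      p_choose_A=("p_choose_A", "mean"),
                      accuracy=("accuracy", "mean"),
                      rt_mean_s=("rt_s", "mean"),
                      confidence_mean=("confidence", "mean")))
    fit = PsychometricModel.from_dataframe(t).fit()
    return BehaviorSummary(per_level=per_level, fit=fit)
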