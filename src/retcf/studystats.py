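"""Statistics of expert odd-one-out and grading studies.

Binomial (Wilson score) confidence intervals for detection proportions,
sample odds ratios from 2x2 tables with Wald intervals, fixed-effects
logistic regression (GLM with binomial family) for the influence of trial
factors, the chance level of an n-alternative forced choice, and a
synthetic-trial simulator for calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint


@dataclass
class Trial:
    rater_id: int
    rater_group: str      # "ophthalmologist" | "ai_researcher"
    arm: str              # "DVC" | "SVC"
    image_class: str
    correct: int

    def __post_init__(self):
        if self.correct not in (0, 1):
            raise ValueError("correct must be 0 or 1")


@dataclass
class ContingencyTable2x2:
    """Rows = condition (exposed / reference), columns = (success, failure)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


def odds_ratio_2x2(table: ContingencyTable2x2, level: float = 0.95,
                   continuity_correction: bool = False) -> dict:
    """Sample odds ratio (a/b)/(c/d) with the Wald log-scale interval."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise ValueError("zero cell; set continuity_correction=True "
                             "to add 0.5 to every cell")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    return {"or": float(orr),
            "ci": (float(np.exp(np.log(orr) - z * se)),
                   float(np.exp(np.log(orr) + z * se))),
            "level": level}


def logistic_glm(trials: pd.DataFrame, predictors: list[str],
                 outcome: str = "correct", level: float = 0.95) -> pd.DataFrame:
    """Fixed-effects logistic regression via IRLS.

    Categorical predictors are dummy-coded against their first level in
    sorted order.  Returns one row per non-intercept coefficient with the
    odds ratio, Wald CI and p-value.
    """
    y = np.asarray(trials[outcome], dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome has fewer than two distinct values")
    for pred in predictors:
        if trials[pred].nunique() < 2:
            raise ValueError(f"predictor {pred!r} is constant (rank deficient)")
    X = pd.get_dummies(trials[predictors], drop_first=True, dtype=float)
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"predictor {col!r} is constant (rank deficient)")
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        fit = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
    except Exception as e:  # perfect separation and friends
        raise ValueError(f"logistic fit failed: {e}") from e
    if np.any(np.abs(fit.params.iloc[1:]) > 15):
        big = X.columns[np.argmax(np.abs(fit.params.iloc[1:].to_numpy()))]
        raise ValueError(f"perfect (or quasi-perfect) separation on predictor {big!r}")
    z = norm.ppf(0.5 + level / 2)
    rows = []
    for name in X.columns:
        beta = fit.params[name]
        se = fit.bse[name]
        rows.append({"predictor": name,
                     "odds_ratio": float(np.exp(beta)),
                     "ci_low": float(np.exp(beta - z * se)),
                     "ci_high": float(np.exp(beta + z * se)),
                     "p_value": float(fit.pvalues[name])})
    return pd.DataFrame(rows)


def chance_level(n_alternatives: int) -> float:
    """Probability of a correct guess in an n-alternative forced choice."""
    if n_alternatives < 1:
        raise ValueError("need at least one alternative")
    return 1.0 / n_alternatives


def simulate_study(skills: dict, n_raters_per_group: dict,
                   trials_per_rater_arm: int, seed: int = 0,
                   image_classes=("healthy", "diseased")) -> pd.DataFrame:
    """Synthetic odd-one-out trials with logistic success probabilities.

    ``skills`` maps (group, arm) -> success probability; outcomes are
    independent Bernoulli draws (fixed-effects design, no rater random
    effects).  Classes alternate evenly across each rater's trials.
    """
    rng = np.random.default_rng([seed, 909])
    rows = []
    rid = 0
    for group, n_raters in n_raters_per_group.items():
        for _ in range(n_raters):
            for arm in sorted({a for (_, a) in skills}):
                p = skills[(group, arm)]
                for j in range(trials_per_rater_arm):
                    rows.append({
                        "rater_id": rid,
                        "rater_group": group,
                        "arm": arm,
                        "image_class": image_classes[j % len(image_classes)],
                        "correct": int(rng.uniform() < p),
                    })
            rid += 1
    return pd.DataFrame(rows)


def trials_to_table(trials: pd.DataFrame, factor: str, exposed: str,
                    outcome: str = "correct") -> ContingencyTable2x2:
    """Collapse trials into a 2x2 table: exposed level vs all others."""
    is_exp = trials[factor] == exposed
    a = int(((trials[outcome] == 1) & is_exp).sum())
    b = int(((trials[outcome] == 0) & is_exp).sum())
    c = int(((trials[outcome] == 1) & ~is_exp).sum())
    d = int(((trials[outcome] == 0) & ~is_exp).sum())
    return ContingencyTable2x2(a, b, c, d)
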