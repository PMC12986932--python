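"""Covariate analysis: score vs age, sex, BMI and smoking.

The adherence score is regressed on covariates outside the index itself
with ordinary least squares (classical standard errors), and smokers are
compared with non-smokers by Welch's t-test (a Mann–Whitney alternative is
available for skewed score distributions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu, ttest_ind

__all__ = ["RegressionResult", "ols_fit", "smoking_contrast", "design_from_records"]


@dataclass(frozen=True)
class RegressionResult:
    terms: dict[str, dict[str, float]]   # term -> estimate, se, t, p
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms).T[["estimate", "se", "t", "p"]]


def design_from_records(records) -> pd.DataFrame:
    """Design frame (age, sex, bmi, smoking) from ResponseRecords; sex and
    smoking enter as 0/1 indicators (female=0/male=1, non-smoker=0)."""
    return pd.DataFrame(
        {
            "age": [r.age for r in records],
            "sex": [int(r.sex == "male") for r in records],
            "bmi": [r.bmi for r in records],
            "smoking": [int(r.smoking) for r in records],
        }
    )


def ols_fit(score, covariates: pd.DataFrame) -> RegressionResult:
    """OLS of the adherence score on a covariate design (intercept added).

    Rejects rank-deficient designs, naming the offending columns.
    """
    y = np.asarray(score, dtype=float)
    X = pd.DataFrame(covariates).astype(float)
    if len(y) != len(X):
        raise ValueError("score and design have different lengths")
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(Xd.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; offending column(s): {bad}")
    fit = sm.OLS(y, Xd).fit()
    terms = {
        ("intercept" if name == "const" else name): {
            "estimate": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
        }
        for name in Xd.columns
    }
    return RegressionResult(terms=terms, r_squared=float(fit.rsquared), n=len(y))


def smoking_contrast(
    score, smoking, method: str = "welch"
) -> dict[str, float]:
    """Two-sample comparison of adherence scores by smoking status.

    Returns the smoker-minus-non-smoker mean difference and the p-value of
    Welch's t-test (``method="welch"``) or the Mann–Whitney U test
    (``method="rank"``).
    """
    score = np.asarray(score, dtype=float)
    smoking = np.asarray(smoking, dtype=bool)
    smokers, others = score[smoking], score[~smoking]
    if len(smokers) < 2 or len(others) < 2:
        raise ValueError("each smoking group needs at least 2 respondents")
    diff = float(smokers.mean() - others.mean())
    if method == "welch":
        p = float(ttest_ind(smokers, others, equal_var=False).pvalue)
    elif method == "rank":
        p = float(mannwhitneyu(smokers, others, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"difference": diff, "p": p}
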