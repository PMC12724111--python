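"""Covariate-adjusted between-arm differences.

The working model for every outcome (costs, SDQ, QALYs) is a linear
regression of the outcome on arm, the relevant baseline measurements
(cost, SDQ, utility) and the four minimisation factors, with a random
intercept for recruiting site.  The arm coefficient is the adjusted
intervention-minus-control difference; Wald 95% intervals use the
mixed-model asymptotics (n is in the hundreds and reported intervals
are symmetric).  Complete-case rows only, defined per analysis.  A
single site, or a failed/degenerate mixed fit, falls back to OLS with a
logged warning; a genuinely singular design raises, naming the
collinear columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

MINIMISATION_FACTORS = ("disorder", "age_group", "asd", "intellectual_disability")
_Z95 = stats.norm.ppf(0.975)


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient."""


@dataclass
class AdjustmentSpec:
    """What to regress and on what.

    ``baseline_covariates`` are continuous baseline columns (e.g.
    cost_baseline_3m, sdq_0, utility_cyp_0); minimisation factors enter
    as treatment-coded categoricals with fixed reference levels
    (anxiety, <11, no, no).
    """

    outcome: str
    baseline_covariates: list = field(default_factory=list)
    minimisation_factors: tuple = MINIMISATION_FACTORS
    cluster: str = "site_id"
    estimator: str = "mixed_random_intercept"  # or "ols"

    def __post_init__(self):
        if self.outcome in self.baseline_covariates:
            raise ValueError("outcome cannot also be a covariate")
        if self.estimator not in ("mixed_random_intercept", "ols"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    def formula(self) -> str:
        terms = ["treat"]
        terms += list(self.baseline_covariates)
        for f in self.minimisation_factors:
            if f == "disorder":
                terms.append("C(disorder, Treatment('anxiety'))")
            elif f == "age_group":
                terms.append("C(age_group, Treatment('<11'))")
            else:
                terms.append(f)
        return f"{self.outcome} ~ " + " + ".join(terms)


@dataclass
class DifferenceEstimate:
    """Adjusted intervention-minus-control difference with Wald 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model_tag: str

    def __post_init__(self):
        assert self.ci_low <= self.estimate <= self.ci_high


def _complete_cases(dataset: pd.DataFrame, spec: AdjustmentSpec) -> pd.DataFrame:
    cols = (
        [spec.outcome]
        + list(spec.baseline_covariates)
        + list(spec.minimisation_factors)
        + ["arm", spec.cluster]
    )
    missing_cols = [c for c in cols if c not in dataset.columns]
    if missing_cols:
        raise KeyError(f"dataset lacks columns {missing_cols}")
    df = dataset[cols].dropna().copy()
    df["treat"] = (df["arm"] == "intervention").astype(int)
    return df


def _diagnose_collinearity(df: pd.DataFrame, formula: str) -> list:
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    names = list(X.columns)
    kept: list = []
    redundant = []
    M = X.to_numpy()
    for j, name in enumerate(names):
        trial_cols = kept + [j]
        if np.linalg.matrix_rank(M[:, trial_cols]) == len(trial_cols):
            kept.append(j)
        else:
            redundant.append(name)
    return redundant


def adjusted_difference(dataset: pd.DataFrame, spec: AdjustmentSpec) -> DifferenceEstimate:
    """Arm coefficient from the adjusted linear model on complete cases."""
    df = _complete_cases(dataset, spec)
    arm_counts = df["treat"].value_counts()
    if len(arm_counts) < 2 or arm_counts.min() < 2:
        raise ValueError(
            f"need >=2 complete observations per arm for {spec.outcome!r}; "
            f"got {arm_counts.to_dict()}"
        )
    formula = spec.formula()

    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        redundant = _diagnose_collinearity(df, formula)
        raise SingularDesignError(
            f"design for {spec.outcome!r} is singular; collinear columns: {redundant}"
        )

    estimator = spec.estimator
    n_sites = df[spec.cluster].nunique()
    if estimator == "mixed_random_intercept" and n_sites < 2:
        logger.warning(
            "single site in complete cases for %s; falling back to OLS", spec.outcome
        )
        estimator = "ols"

    tag = estimator
    if estimator == "mixed_random_intercept":
        est = se = float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell"):
                try:
                    model = smf.mixedlm(formula, df, groups=df[spec.cluster])
                    res = model.fit(reml=True, method=method, maxiter=500)
                    est = float(res.params["treat"])
                    se = float(res.bse["treat"])
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.isfinite(est) and np.isfinite(se) and se > 0:
                    break
        if not (np.isfinite(est) and np.isfinite(se) and se > 0):
            logger.info("degenerate mixed fit for %s; falling back to OLS", spec.outcome)
            estimator = "ols"
            tag = "ols_fallback"

    if estimator == "ols":
        res = sm.OLS(y.to_numpy().ravel(), X.to_numpy()).fit()
        j = list(X.columns).index("treat")
        est = float(res.params[j])
        se = float(res.bse[j])

    p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else 0.0
    return DifferenceEstimate(
        estimate=est,
        se=se,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        p_value=p,
        n_used=len(df),
        model_tag=tag,
    )


def unadjusted_means(dataset: pd.DataFrame, outcome: str) -> dict:
    """Per-arm mean/SD and the raw difference, with a Welch t-test.

    Parametric comparison of arithmetic means is the standard choice for
    cost data even when skewed, since the mean is the decision-relevant
    statistic.
    """
    df = dataset[[outcome, "arm"]].dropna()
    groups = {a: g[outcome].to_numpy(dtype=float) for a, g in df.groupby("arm")}
    for a in ("intervention", "control"):
        if a not in groups or len(groups[a]) == 0:
            raise ValueError(f"no observations in arm {a!r} for {outcome!r}")
    xi, xc = groups["intervention"], groups["control"]
    t, p = stats.ttest_ind(xi, xc, equal_var=False)
    return {
        "outcome": outcome,
        "mean_intervention": float(xi.mean()),
        "sd_intervention": float(xi.std(ddof=1)) if len(xi) > 1 else float("nan"),
        "n_intervention": int(len(xi)),
        "mean_control": float(xc.mean()),
        "sd_control": float(xc.std(ddof=1)) if len(xc) > 1 else float("nan"),
        "n_control": int(len(xc)),
        "difference": float(xi.mean() - xc.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
    }
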