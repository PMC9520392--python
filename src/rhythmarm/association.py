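"""Activity Rhythm Metric scoring and cohort-level association tests.

The ARM for a participant is the sum of the two hour-of-day intercept
variances from their fitted CT-HMM, ARM = sigma_1^2 + sigma_2^2; larger
values mean more regular daily routines.  Participants whose EM fit did
not converge carry no ARM and are excluded from the cohort table.

Associations with sleep, mood and demographic covariates use nested
Gaussian linear models fitted by maximum likelihood: for each covariate
the full model ARM ~ age + sex + covariate is compared against the null
ARM ~ age + sex with a 1-df likelihood ratio test (age and sex are each
tested controlling only for the other).  Tests are two-sided and
unadjusted; complete-case per covariate.  Both raw and age/sex-adjusted
(partial) Pearson correlations are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cthmm import FittedModel


@dataclass
class ArmScore:
    participant_id: str
    arm: float | None  # None when the fit did not converge
    sigma1_sq: float
    sigma2_sq: float
    converged: bool


@dataclass
class LrtResult:
    covariate_name: str
    coefficient: float
    lrt_stat: float
    df: int
    p_value: float
    n_used: int
    pearson_r: float
    partial_r: float


def compute_arm(model: FittedModel, participant_id: str = "") -> ArmScore:
    """ARM = sigma_1^2 + sigma_2^2, withheld when the fit did not converge."""
    arm = model.params.sigma1_sq + model.params.sigma2_sq
    return ArmScore(
        participant_id=participant_id,
        arm=float(arm) if model.converged else None,
        sigma1_sq=float(model.params.sigma1_sq),
        sigma2_sq=float(model.params.sigma2_sq),
        converged=model.converged,
    )


def build_cohort_table(scores: list[ArmScore], covariates: pd.DataFrame) -> pd.DataFrame:
    """One row per converged participant: ARM joined to the covariate table."""
    rows = [
        {"participant_id": s.participant_id, "arm": s.arm}
        for s in scores
        if s.converged and s.arm is not None
    ]
    arm_df = pd.DataFrame(rows, columns=["participant_id", "arm"])
    return arm_df.merge(covariates, on="participant_id", how="left")


def _ols_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    model = sm.OLS(y, X).fit()  # OLS llf is the Gaussian ML log-likelihood
    return float(model.llf), model.params


def lrt_association(
    cohort: pd.DataFrame,
    covariate: str,
    controls: tuple[str, ...] = ("age", "sex"),
    outcome: str = "arm",
) -> LrtResult:
    """1-df LRT of `outcome ~ controls + covariate` against `outcome ~ controls`."""
    cols = [outcome, covariate, *controls]
    df = cohort[cols].dropna()
    n = len(df)
    if n < 5:
        raise ValueError(f"need at least 5 complete rows for '{covariate}', got {n}")
    cov = df[covariate].to_numpy(dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError(f"covariate '{covariate}' is constant; design is singular")
    y = df[outcome].to_numpy(dtype=float)
    X_null = sm.add_constant(df[list(controls)].to_numpy(dtype=float))
    X_full = np.column_stack([X_null, cov])
    ll_null, _ = _ols_loglik(y, X_null)
    ll_full, beta = _ols_loglik(y, X_full)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(stats.chi2.sf(lrt, df=1))

    r = float(np.corrcoef(y, cov)[0, 1])
    # partial correlation: residualize both on the controls
    res_y = y - X_null @ np.linalg.lstsq(X_null, y, rcond=None)[0]
    res_c = cov - X_null @ np.linalg.lstsq(X_null, cov, rcond=None)[0]
    denom = res_y.std() * res_c.std()
    partial = float(np.mean(res_y * res_c) / denom) if denom > 0 else np.nan

    return LrtResult(
        covariate_name=covariate,
        coefficient=float(beta[-1]),
        lrt_stat=float(lrt),
        df=1,
        p_value=p,
        n_used=n,
        pearson_r=r,
        partial_r=partial,
    )


def age_sex_tests(cohort: pd.DataFrame) -> tuple[LrtResult, LrtResult]:
    """Age tested controlling sex, and sex tested controlling age."""
    return (
        lrt_association(cohort, "age", controls=("sex",)),
        lrt_association(cohort, "sex", controls=("age",)),
    )


DEFAULT_COVARIATES = (
    "mean_sleep_hours",
    "psqi_sleep_component",
    "sd_bed_time",
    "sd_wake_time",
    "mean_mood",
    "bdi",
)


def associate_all(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Run the standard battery of LRTs; optional Benjamini-Hochberg column."""
    results: list[LrtResult] = []
    for cov in covariates:
        if cov not in cohort.columns or cohort[cov].dropna().shape[0] < 5:
            continue
        results.append(lrt_association(cohort, cov))
    results.extend(age_sex_tests(cohort))
    out = pd.DataFrame(
        {
            "covariate": [r.covariate_name for r in results],
            "coefficient": [r.coefficient for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "n_used": [r.n_used for r in results],
            "pearson_r": [r.pearson_r for r in results],
            "partial_r": [r.partial_r for r in results],
        }
    )
    if bh_adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
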