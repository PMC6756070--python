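"""Five-year overall-survival analysis of amplification-defined groups.

Records carry time in years and an event indicator; patients without an
event within the horizon are administratively censored at the horizon
(default 5 years).  Estimation is delegated to lifelines: product-limit
(Kaplan-Meier) curves, the log-rank test, and Cox proportional-hazards
fits with Efron handling of tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from incis.stats import TestResult

__all__ = [
    "HazardEstimate",
    "censor_at_horizon",
    "km_estimate",
    "logrank",
    "cox_fit",
    "prepare_covariates",
]


@dataclass(frozen=True)
class HazardEstimate:
    covariate: str
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    model: str  # "univariable" or "multivariable"

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.hr <= self.ci_upper):
            raise ValueError("confidence interval must contain the hazard ratio")


def censor_at_horizon(records: pd.DataFrame, horizon: float = 5.0) -> pd.DataFrame:
    """Cap follow-up at the horizon; events beyond it become censored."""
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    out = records.copy()
    late = out["time"] > horizon
    out.loc[late, "event"] = False
    out.loc[late, "time"] = horizon
    out["event"] = out["event"].astype(bool)
    return out


def km_estimate(
    records: pd.DataFrame, group_col: str = "group", at: float = 5.0
) -> dict[str, dict]:
    """Kaplan-Meier fit per group with the survival probability at ``at``."""
    out: dict[str, dict] = {}
    for name, sub in records.groupby(group_col):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(name))
        out[str(name)] = {
            "n": int(len(sub)),
            "events": int(sub["event"].sum()),
            "survival_at": float(kmf.predict(at)),
            "fitter": kmf,
        }
    if not out:
        raise ValueError("no groups with records")
    return out


def logrank(records: pd.DataFrame, group_col: str = "group") -> TestResult:
    """Log-rank chi-square test across groups (1 df for two groups)."""
    groups = records[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(
        records["time"], records[group_col], records["event"]
    )
    return TestResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value), method="logrank"
    )


def prepare_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Encode the standard covariates for proportional-hazards modelling.

    Age is dichotomized above/below the cohort median; stage enters as
    indicator contrasts with stage I as reference; gender and localization
    as binary indicators.
    """
    out = pd.DataFrame(index=records.index)
    if "age" in records:
        out["age_above_median"] = (records["age"] > records["age"].median()).astype(int)
    if "gender" in records:
        out["gender_male"] = (records["gender"].astype(str).str.lower() == "male").astype(int)
    if "localization" in records:
        out["localization_proximal"] = (
            records["localization"].astype(str).str.lower() == "proximal"
        ).astype(int)
    if "stage" in records:
        stage = records["stage"].astype(str)
        out["stage_II"] = (stage == "II").astype(int)
        out["stage_III"] = (stage == "III").astype(int)
    return out


def _fit_one(df: pd.DataFrame, model: str) -> list[HazardEstimate]:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(f"Cox fit failed ({model}): {exc}") from exc
    summary = cph.summary
    return [
        HazardEstimate(
            covariate=str(idx),
            hr=float(row["exp(coef)"]),
            ci_lower=float(row["exp(coef) lower 95%"]),
            ci_upper=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            model=model,
        )
        for idx, row in summary.iterrows()
    ]


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    model: str = "univariable",
) -> list[HazardEstimate]:
    """Cox proportional-hazards fit(s) with Wald intervals.

    ``records`` must contain ``time``, ``event`` and the covariate columns
    (already numeric, e.g. from :func:`prepare_covariates`).  Univariable
    mode fits each covariate in its own model; multivariable mode fits one
    joint model.
    """
    if int(records["event"].sum()) < 1:
        raise ValueError("need at least one event")
    for cov in covariates:
        if records[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    base = records[["time", "event"]].copy()
    base["event"] = base["event"].astype(int)
    if model == "multivariable":
        df = pd.concat([base, records[covariates]], axis=1)
        return _fit_one(df, model)
    if model != "univariable":
        raise ValueError(f"unknown model: {model}")
    estimates: list[HazardEstimate] = []
    for cov in covariates:
        df = pd.concat([base, records[[cov]]], axis=1)
        estimates.extend(_fit_one(df, model))
    return estimates
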