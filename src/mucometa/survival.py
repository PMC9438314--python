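"""Recurrence-free survival association of pathway activity and clinical variables.

Pathway activity scores are dichotomised at the first quartile (Low = at or
below Q1, High = above).  Clinical variables use WHO BMI categories
(>= 25 kg/m2 = Overweight/Obese) and median splits for age and tumor size.
Group comparisons use Kaplan-Meier product-limit curves with the two-group
log-rank test; multivariable association uses Cox proportional-hazards
regression (Efron tie handling, via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DegenerateDataError, InvalidParameterError

LOW, HIGH = "Low", "High"
BMI_CUTOFF = 25.0


def categorize_score(scores: pd.Series, quantile: float = 0.25) -> pd.Series:
    """Label scores at or below the first quartile Low, the rest High.

    The quartile uses the linear-interpolation definition; ties at the
    cutoff go to Low.  Monotone transforms of the scores leave the labels
    unchanged (the split is rank-based).
    """
    if len(scores) < 4:
        raise InvalidParameterError("need >= 4 samples to categorize at a quartile")
    if scores.nunique() == 1:
        raise DegenerateDataError("all scores equal: categorization degenerate")
    q1 = float(np.quantile(scores.to_numpy(float), quantile))
    labels = pd.Series(np.where(scores <= q1, LOW, HIGH), index=scores.index,
                       name=f"{scores.name or 'score'}_group")
    if labels.nunique() == 1:
        raise DegenerateDataError("quartile split produced a single group")
    return labels


def categorize_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Dichotomise BMI (WHO >= 25), age and tumor size (cohort medians)."""
    required = ["bmi", "age", "tumor_size_cm"]
    missing = [v for v in required if v not in clinical.columns]
    if missing:
        raise InvalidParameterError(f"clinical table lacks variables: {missing}")
    out = pd.DataFrame(index=clinical.index)
    out["bmi_group"] = np.where(clinical["bmi"] >= BMI_CUTOFF,
                                "Overweight/Obese", "Underweight/Normal weight")
    for var, name in (("age", "age_group"), ("tumor_size_cm", "tumor_size_group")):
        values = clinical[var].astype(float)
        if values.nunique() == 1:
            raise DegenerateDataError(f"{var}: all values equal, median split degenerate")
        med = values.median()
        out[name] = np.where(values <= med, LOW, HIGH)
    return out


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier curves per label plus the two-group log-rank test."""

    curves: dict  # label -> DataFrame(timeline, survival, ci_lower, ci_upper)
    statistic: float
    p_value: float
    n_per_group: dict

    def summary(self) -> str:
        groups = ", ".join(f"{k} (n={v})" for k, v in self.n_per_group.items())
        return (f"Kaplan-Meier comparison of {groups}\n"
                f"  log-rank statistic = {self.statistic:.4f}, p = {self.p_value:.4g}")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.curves.items():
            ax.step(curve["timeline"], curve["survival"], where="post", label=label)
        ax.set_xlabel("months")
        ax.set_ylabel("RFS probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


def km_logrank(labels: pd.Series, survival: pd.DataFrame) -> KMResult:
    """Product-limit curves and log-rank test between two labelled groups.

    ``survival`` must have columns ``rfs_months`` and ``rfs_event`` indexed
    like ``labels``.
    """
    common = labels.index.intersection(survival.index)
    labels = labels.loc[common]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise InvalidParameterError(
            f"expected exactly 2 groups, got {uniq or 'none'}"
        )
    times = survival.loc[common, "rfs_months"].astype(float)
    events = survival.loc[common, "rfs_event"].astype(bool)
    curves, ns = {}, {}
    for label in uniq:
        mask = labels == label
        if mask.sum() == 0:
            raise InvalidParameterError(f"group {label!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(label))
        ci = kmf.confidence_interval_survival_function_
        curves[label] = pd.DataFrame({
            "timeline": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        })
        ns[label] = int(mask.sum())
    mask = labels == uniq[0]
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=float(res.p_value), n_per_group=ns)


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratios with 95% CIs and Wald p-values per covariate."""

    table: pd.DataFrame  # hazard_ratio, ci_lower, ci_upper, p_value, coef
    n: int
    n_events: int

    def summary(self) -> str:
        lines = [f"Cox proportional hazards (n={self.n}, events={self.n_events})"]
        for cov, row in self.table.iterrows():
            lines.append(
                f"  {cov}: HR = {row.hazard_ratio:.3f} "
                f"[{row.ci_lower:.3f}, {row.ci_upper:.3f}], p = {row.p_value:.4g}"
            )
        return "\n".join(lines)


def cox_ph(covariates: pd.DataFrame, survival: pd.DataFrame) -> CoxResult:
    """Fit a Cox model of RFS on the given covariate frame.

    Categorical/boolean covariates must already be numeric (0/1).  Raises
    on zero events or constant covariates; convergence failures (e.g.
    perfect separation) surface as :class:`DegenerateDataError`.
    """
    common = covariates.index.intersection(survival.index)
    data = covariates.loc[common].astype(float).copy()
    data["rfs_months"] = survival.loc[common, "rfs_months"].astype(float)
    data["rfs_event"] = survival.loc[common, "rfs_event"].astype(bool).astype(int)
    if data["rfs_event"].sum() < 1:
        raise DegenerateDataError("no events: Cox model undefined")
    constant = [c for c in covariates.columns if data[c].nunique() <= 1]
    if constant:
        raise DegenerateDataError(f"constant covariates: {constant}")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="rfs_months", event_col="rfs_event")
    except Exception as exc:  # lifelines raises several convergence errors
        raise DegenerateDataError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame({
        "coef": s["coef"],
        "hazard_ratio": s["exp(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p_value": s["p"],
    })
    table.index.name = "covariate"
    return CoxResult(table=table, n=len(data), n_events=int(data["rfs_event"].sum()))
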