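"""Survival and treatment-response statistics.

Links subtype labels to outcomes: Kaplan-Meier estimation with median
survival, log-rank group comparison, univariate and multivariate Cox
proportional-hazards regression (Efron tie handling), the 3-month
clinical-benefit rule, and chi-square / Fisher association tests for
contingency tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2_contingency, fisher_exact

__all__ = [
    "CLINICAL_COLUMNS",
    "KmResult",
    "SurvivalComparison",
    "read_clinical",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "clinical_benefit",
    "association_test",
    "compare_survival",
]

CLINICAL_COLUMNS = [
    "patient", "os_months", "os_event", "pfs_months", "pfs_event",
    "best_response", "response_duration_months", "arm", "age", "sex",
    "smoking", "stage", "platinum_sensitive", "n_prior",
]

# best responses that can count as clinical benefit (with >= 3 mo duration)
_BENEFIT_RESPONSES = {"CR", "PR", "SD"}

NOT_REACHED = float("inf")  # distinguished 'median not reached' value


@dataclass
class KmResult:
    """Kaplan-Meier step function and median survival.

    ``median`` is the first time at which S(t) <= 0.5, or ``NOT_REACHED``
    (+inf) when the curve never crosses 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalComparison:
    medians: dict
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV missing columns: {missing}")
    return df


def km_estimate(times, events) -> KmResult:
    """Product-limit survival estimate with median survival."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no subjects")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    med = kmf.median_survival_time_
    return KmResult(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        median=NOT_REACHED if np.isinf(med) else float(med),
    )


def logrank_test(*groups) -> tuple[float, float]:
    """Log-rank test over >= 2 groups of ``(times, events)`` pairs.

    Returns ``(chi_square, p_value)`` with df = n_groups - 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    all_t, all_e, all_g = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if len(t) == 0:
            raise ValueError(f"group {gi} is empty")
        if (t <= 0).all() and len(t) > 0 and (t == 0).all():
            raise ValueError(f"group {gi} has all zero-time subjects")
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(len(t), gi))
    res = multivariate_logrank_test(
        np.concatenate(all_t), np.concatenate(all_g), np.concatenate(all_e)
    )
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    event_type: str = "os",
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron ties).

    Returns a frame indexed by covariate with columns
    ``hr, ci_low, ci_high, p_value``. Raises when there are no events or
    a covariate is constant; non-convergence surfaces as a ValueError.
    """
    if event_type not in ("os", "pfs"):
        raise ValueError("event_type must be 'os' or 'pfs'")
    tcol, ecol = f"{event_type}_months", f"{event_type}_event"
    df = records[[tcol, ecol, *covariates]].dropna()
    if df[ecol].sum() == 0:
        raise ValueError("no events")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=tcol, event_col=ecol)
    except Exception as exc:  # monotone likelihood etc.
        raise ValueError(f"Cox model did not converge: {exc}") from exc
    summ = cph.summary
    return pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p_value": summ["p"],
        }
    )


def clinical_benefit(records: pd.DataFrame, group_col: str | None = None):
    """Clinical-benefit rate: CR/PR/SD maintained for >= 3 months.

    Records with a benefit-eligible response but missing duration are
    excluded with a warning. With ``group_col``, returns a per-group
    Series of rates; otherwise a single float.
    """
    df = records.copy()
    eligible = df["best_response"].isin(_BENEFIT_RESPONSES)
    bad = eligible & df["response_duration_months"].isna()
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} record(s) with CR/PR/SD but missing duration "
            "excluded"
        )
        df = df[~bad]
    benefit = df["best_response"].isin(_BENEFIT_RESPONSES) & (
        df["response_duration_months"] >= 3.0
    )
    if group_col is None:
        return float(benefit.mean())
    return benefit.groupby(df[group_col]).mean()


def association_test(table, method: str = "auto") -> tuple[float, float, str]:
    """Chi-square association test with Fisher fallback.

    With ``method='auto'``, a 2x2 table with any expected cell below 5
    uses the two-tailed Fisher exact test; otherwise chi-square. Either
    test can be forced explicitly. Returns ``(statistic, p, method)``
    where the statistic is chi-square or, for Fisher, the odds ratio.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    if method not in ("auto", "fisher", "chi-square"):
        raise ValueError("method must be 'auto', 'fisher' or 'chi-square'")
    if method == "auto":
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        method = (
            "fisher" if table.shape == (2, 2) and (expected < 5).any()
            else "chi-square"
        )
    if method == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher exact test requires a 2x2 table")
        odds, p = fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi-square"


def compare_survival(
    records: pd.DataFrame,
    group_col: str,
    event_type: str = "os",
) -> SurvivalComparison:
    """Two-group survival comparison: medians, HR with 95% CI, log-rank p."""
    tcol, ecol = f"{event_type}_months", f"{event_type}_event"
    groups = sorted(records[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups in {group_col!r}")
    medians = {}
    arms = []
    for g in groups:
        sub = records[records[group_col] == g]
        medians[g] = km_estimate(sub[tcol], sub[ecol]).median
        arms.append((sub[tcol].to_numpy(), sub[ecol].to_numpy()))
    _, p = logrank_test(*arms)
    indicator = (records[group_col] == groups[1]).astype(int)
    cox_df = records[[tcol, ecol]].assign(group=indicator)
    cox = cox_ph(cox_df.rename(columns={"group": "_grp"}), ["_grp"], event_type)
    row = cox.loc["_grp"]
    return SurvivalComparison(
        medians=medians,
        hazard_ratio=float(row["hr"]),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
        logrank_p=p,
    )
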