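"""Clinical statistics: TMB cutoff determination and survival analysis.

The cutoff procedure mirrors clinical-biomarker practice for immune
checkpoint inhibitor (ICI) cohorts: patients are labeled DCB (durable
clinical benefit: complete/partial response, or stable disease lasting
>= 24 weeks) versus NDB, an ROC curve of TMB against DCB is swept over
candidate integer cutoffs, the Youden J (sensitivity + specificity - 1)
maximum picks the primary cutoff, and a log-rank scan over the same grid
corroborates it on overall survival.  Kaplan-Meier estimation, the
log-rank test and Cox proportional-hazards regression go through
lifelines; Welch's t-test and Fisher's exact test through scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

DCB_RESPONSES = {"CR", "PR"}
NDB_RESPONSES = {"PD"}
SD_DURABLE_WEEKS = 24.0


def derive_dcb(response: str, sd_duration_weeks: Optional[float] = None) -> bool:
    """Durable clinical benefit: CR/PR, or SD sustained >= 24 weeks."""
    if response in DCB_RESPONSES:
        return True
    if response in NDB_RESPONSES:
        return False
    if response == "SD":
        if sd_duration_weeks is None or (
            isinstance(sd_duration_weeks, float) and np.isnan(sd_duration_weeks)
        ):
            raise ValueError("SD requires a duration to derive DCB/NDB")
        return float(sd_duration_weeks) >= SD_DURABLE_WEEKS
    raise ValueError(f"unknown response category {response!r}")


@dataclass
class ClinicalCohort:
    """Per-patient TMB, benefit label, survival endpoints and covariates."""

    frame: pd.DataFrame  # columns: tmb, dcb, os_months, os_event, pfs_months,
    #                       pfs_event, age, gender, drug, cancer_type

    def __post_init__(self) -> None:
        for col in ("os_months", "pfs_months"):
            if col in self.frame and (self.frame[col] < 0).any():
                raise ValueError(f"negative times in {col}")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ClinicalCohort":
        df = df.copy()
        df["dcb"] = [
            derive_dcb(r, d)
            for r, d in zip(df["response"], df.get("sd_duration_weeks"))
        ]
        return cls(df)

    @property
    def tmb(self) -> np.ndarray:
        return self.frame["tmb"].to_numpy(dtype=float)

    @property
    def dcb(self) -> np.ndarray:
        return self.frame["dcb"].to_numpy(dtype=bool)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]):
    """ROC of a score against a binary label.

    Returns (auc, sweep) where sweep is a DataFrame with one row per distinct
    score value: threshold, sensitivity, specificity, youden_j for the rule
    ``score >= threshold -> positive``.  The AUC is the Mann-Whitney
    probability that a positive outscores a negative (ties count 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # Mann-Whitney U via midranks
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.unique(scores)
    rows = []
    for t in thresholds:
        pred = scores >= t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        rows.append((t, sens, spec, sens + spec - 1))
    sweep = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "youden_j"])
    return float(auc), sweep


def logrank_test(
    times: Sequence[float], events: Sequence[bool], group: Sequence[bool]
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        times[group], times[~group], events[group], events[~group]
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a DataFrame (time, survival); without censoring this equals the
    empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


@dataclass
class CutoffResult:
    cutoff: float
    auc: float
    youden_j: float
    logrank_chisq: float
    logrank_p: float
    n_high: int
    n_low: int
    informative: bool = True
    scan: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def select_cutoff(
    cohort: ClinicalCohort,
    candidates: Optional[Sequence[float]] = None,
    endpoint: str = "os",
    criterion: str = "youden",
    min_group: int = 2,
) -> CutoffResult:
    """Pick the TMB cutoff separating benefit from non-benefit patients.

    Primary criterion: maximize Youden J of the rule ``tmb >= cutoff``
    against DCB over the candidate grid (integers 1..20 by default); ties
    break toward the smaller cutoff.  The log-rank statistic on the chosen
    endpoint is reported across the whole grid as corroboration; set
    ``criterion="logrank"`` to instead pick the minimal-p cutoff (beware
    multiplicity — the grid scan is not corrected).
    """
    if candidates is None:
        candidates = list(range(1, 21))
    tmb, dcb = cohort.tmb, cohort.dcb
    if dcb.all() or (~dcb).all():
        raise ValueError("degenerate cohort: a single benefit class")
    auc, _ = roc_auc(tmb, dcb)
    tcol = f"{endpoint}_months"
    ecol = f"{endpoint}_event"
    times = cohort.frame[tcol].to_numpy(dtype=float)
    events = cohort.frame[ecol].to_numpy(dtype=bool)

    rows = []
    n_pos, n_neg = int(dcb.sum()), int((~dcb).sum())
    for c in candidates:
        high = tmb >= c
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        sens = (high & dcb).sum() / n_pos
        spec = (~high & ~dcb).sum() / n_neg
        j = sens + spec - 1
        chisq, p = logrank_test(times, events, high)
        rows.append((float(c), j, chisq, p, int(high.sum()), int((~high).sum())))
    if not rows:
        raise ValueError("no candidate cutoff leaves both groups populated")
    scan = pd.DataFrame(
        rows, columns=["cutoff", "youden_j", "logrank_chisq", "logrank_p", "n_high", "n_low"]
    )
    if criterion == "logrank":
        best = scan.loc[scan["logrank_p"].idxmin()]
    else:
        # stable argmax with ties toward the smaller cutoff (scan is sorted)
        best = scan.loc[scan["youden_j"].idxmax()]
    return CutoffResult(
        cutoff=float(best["cutoff"]),
        auc=auc,
        youden_j=float(best["youden_j"]),
        logrank_chisq=float(best["logrank_chisq"]),
        logrank_p=float(best["logrank_p"]),
        n_high=int(best["n_high"]),
        n_low=int(best["n_low"]),
        informative=bool(best["youden_j"] > 0.1),
        scan=scan,
    )


def cox_multivariate(
    cohort: ClinicalCohort,
    cutoff: float,
    covariates: Sequence[str] = ("gender", "age", "drug", "cancer_type"),
    endpoint: str = "os",
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit of TMB group + covariates.

    Categorical covariates are one-hot encoded (first level dropped); age is
    dichotomized at its median.  Returns a DataFrame with hazard ratios and
    95% confidence intervals; raises on zero events, flags (but does not
    hide) non-convergence via lifelines' own warnings.
    """
    df = cohort.frame
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    if df[ecol].sum() == 0:
        raise ValueError("no events; Cox model cannot be fit")
    X = pd.DataFrame(
        {
            "tmb_high": (df["tmb"] >= cutoff).astype(float),
            tcol: df[tcol].astype(float),
            ecol: df[ecol].astype(int),
        }
    )
    for cov in covariates:
        if cov == "age":
            X["age_high"] = (df["age"] >= df["age"].median()).astype(float)
        else:
            dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True)
            for col in dummies.columns:
                X[col] = dummies[col].astype(float)
    cph = CoxPHFitter()
    cph.fit(X, duration_col=tcol, event_col=ecol)
    out = cph.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    out = out.rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_lo",
            "exp(coef) upper 95%": "hr_hi",
        }
    )
    return out


def compare_tmb_groups(
    tmb_a: Sequence[float], tmb_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test between two TMB groups (t statistic, p)."""
    a = np.asarray(tmb_a, dtype=float)
    b = np.asarray(tmb_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fisher_exact_rates(
    success_a: int, n_a: int, success_b: int, n_b: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 rate comparison (odds ratio, p)."""
    table = [[success_a, n_a - success_a], [success_b, n_b - success_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
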