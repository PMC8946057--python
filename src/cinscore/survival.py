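"""Median stratification, log-rank / Cox survival comparison, response tests.

Samples are split at their cohort's median CIN score into high/low groups
(ties at the median go to the low group by default).  Group survival is
compared with the standard two-group log-rank chi-squared test (implemented
here), a univariate Cox proportional-hazards model for the high-group
indicator (delegated to lifelines), and Kaplan-Meier five-year survival read
at 1826 days.  Therapy response is compared between responders and
non-responders with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

FIVE_YEARS_DAYS = 1826.0


def stratify_by_median(
    scores: pd.Series,
    cohorts: Optional[pd.Series] = None,
    ties_to: str = "low",
) -> pd.Series:
    """Label each sample 'high' or 'low' relative to its cohort median score.

    ``ties_to`` decides where samples exactly at the median go.  Constant
    scores within a cohort are an error (no stratification exists).
    """
    if ties_to not in ("low", "high"):
        raise ValueError("ties_to must be 'low' or 'high'")
    scores = pd.Series(scores, dtype=float)

    def _split(v: pd.Series) -> pd.Series:
        if v.nunique() < 2:
            raise ValueError("cannot stratify a constant score")
        med = v.median()
        high = v > med if ties_to == "low" else v >= med
        return pd.Series(np.where(high, "high", "low"), index=v.index)

    if cohorts is None:
        return _split(scores)
    cohorts = pd.Series(cohorts).reindex(scores.index)
    parts = [_split(v) for _, v in scores.groupby(cohorts)]
    return pd.concat(parts).reindex(scores.index)


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> Tuple[float, float]:
    """Two-group log-rank test (standard chi-squared form).

    ``group`` is a boolean/0-1 indicator of the high group.  Returns
    (chi-squared statistic, p-value).  Invariant under sample order.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order]

    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n_tot = at_risk.sum()
        n1 = group[at_risk].sum()
        dying = (time == t) & (event == 1)
        d_tot = dying.sum()
        d1 = (dying & (group == 1)).sum()
        if n_tot < 2:
            continue
        e1 = d_tot * n1 / n_tot
        v = d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class SurvivalResult:
    """Log-rank, Cox hazard ratio and Kaplan-Meier summary for one split."""

    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float
    n_high: int
    n_low: int
    events_high: int
    events_low: int
    five_year_high: float
    five_year_low: float
    reliable: bool
    endpoint: str = ""
    cohort: str = ""


def _km_at(time, event, horizon: float) -> float:
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(time, event_observed=event)
    return float(km.predict(horizon))


def survival_compare(
    time,
    event,
    group,
    endpoint: str = "",
    cohort: str = "",
) -> SurvivalResult:
    """Compare high vs low groups: log-rank, univariate Cox HR, 5-y survival.

    ``group`` holds 'high'/'low' labels (or a boolean high indicator).  A
    group without any observed event makes the hazard ratio unidentifiable;
    the result is then flagged unreliable.
    """
    from lifelines import CoxPHFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g = np.asarray(group)
    high = (g == "high") | (g == True) | (g == 1)  # noqa: E712
    if high.all() or (~high).all():
        raise ValueError("both groups must be non-empty")

    ev_high = int(event[high].sum())
    ev_low = int(event[~high].sum())
    reliable = ev_high > 0 and ev_low > 0

    chi2, p = logrank_test(time, event, high.astype(int))

    hr = hr_lo = hr_hi = cox_p = float("nan")
    if reliable:
        df = pd.DataFrame({"time": time, "event": event, "high": high.astype(int)})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = cph.confidence_intervals_
        # a near-unidentifiable bound may overflow to an infinite HR limit
        with np.errstate(over="ignore"):
            hr_lo = float(np.exp(ci.iloc[0, 0]))
            hr_hi = float(np.exp(ci.iloc[0, 1]))
        cox_p = float(cph.summary.loc["high", "p"])

    return SurvivalResult(
        logrank_stat=chi2,
        logrank_p=p,
        hazard_ratio=hr,
        hr_ci_low=hr_lo,
        hr_ci_high=hr_hi,
        cox_p=cox_p,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        events_high=ev_high,
        events_low=ev_low,
        five_year_high=_km_at(time[high], event[high], FIVE_YEARS_DAYS),
        five_year_low=_km_at(time[~high], event[~high], FIVE_YEARS_DAYS),
        reliable=reliable,
        endpoint=endpoint,
        cohort=cohort,
    )


def survival_by_cohort(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    score: str = "ncs",
    endpoint: str = "os",
    ties_to: str = "low",
) -> pd.DataFrame:
    """Median-stratified survival comparison within every cohort.

    Stratification uses all scored samples of a cohort; the comparison then
    subsets to samples with a complete (time, event) record for the endpoint.
    """
    s = scores.set_index("sample_id")
    merged = s.join(annotations, how="inner", rsuffix="_ann")
    cohort_col = "cohort" if "cohort" in s.columns else "cohort_ann"
    rows = []
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for cohort, sub in merged.groupby(merged[cohort_col]):
        groups = stratify_by_median(sub[score], ties_to=ties_to)
        complete = sub[tcol].notna() & sub[ecol].notna()
        if complete.sum() < 2:
            continue
        r = survival_compare(
            sub.loc[complete, tcol],
            sub.loc[complete, ecol],
            groups[complete],
            endpoint=endpoint,
            cohort=str(cohort),
        )
        rows.append(r.__dict__)
    return pd.DataFrame(rows)


def response_test(
    scores: pd.Series, labels: pd.Series
) -> Tuple[float, float, float, float]:
    """Wilcoxon rank-sum comparison of scores between response groups.

    Returns (statistic, two-sided p, median responders, median
    non-responders).  Samples with missing labels are dropped; both groups
    must be non-empty.
    """
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).reindex(scores.index)
    ok = labels.notna() & scores.notna()
    scores, labels = scores[ok], labels[ok]
    resp = scores[labels == "responder"]
    nonresp = scores[labels == "non-responder"]
    if len(resp) == 0 or len(nonresp) == 0:
        raise ValueError("both response groups must be non-empty")
    if scores.nunique() < 2:
        return float(len(resp) * len(nonresp) / 2.0), 1.0, float(resp.median()), float(nonresp.median())
    stat, p = stats.mannwhitneyu(resp, nonresp, alternative="two-sided")
    return float(stat), float(p), float(resp.median()), float(nonresp.median())
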