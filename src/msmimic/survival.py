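"""Progression-free survival by molecular subgroup.

Kaplan–Meier product-limit estimation per subgroup and the k-group log-rank
test, with per-group observed and expected event counts exposed so the
O−E accounting can be audited.  The 5-year landmark (60 months) is read from
the right-continuous KM step function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "cohort_report",
]


@dataclass
class KMEstimate:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    required = {"time_months", "event", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if (df["time_months"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return df


def km_estimate(records: pd.DataFrame) -> dict[str, KMEstimate]:
    """Kaplan–Meier curves per group.

    ``records`` needs columns time_months, event, group.  Censored subjects
    tied with events at the same time are, by the product-limit convention,
    censored after the events.
    """
    df = _check_records(records)
    out: dict[str, KMEstimate] = {}
    for group, sub in df.groupby("group", observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        table = kmf.event_table
        times = table.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        out[str(group)] = KMEstimate(
            group=str(group),
            times=times,
            survival=surv,
            at_risk=table["at_risk"].to_numpy(dtype=float),
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return out


@dataclass
class LogRankResult:
    """k-group log-rank test with its O/E bookkeeping."""

    statistic: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.observed.values()) - sum(self.expected.values())) > 1e-9:
            raise ValueError("sum of observed must equal sum of expected")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must be in (0, 1]")


def logrank_test(records: pd.DataFrame, groups: list[str] | None = None) -> LogRankResult:
    """Standard k-group log-rank test.

    At each distinct event time t the events are apportioned to groups by
    their at-risk fractions; the statistic is the quadratic form of O−E with
    the hypergeometric covariance, referred to χ² with k−1 degrees of
    freedom.  Pass ``groups`` to restrict/merge (e.g. a one-vs-rest
    comparison is obtained by relabeling beforehand).
    """
    df = _check_records(records)
    if groups is not None:
        df = df[df["group"].isin(groups)]
    labels = sorted(df["group"].unique(), key=str)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank requires at least two groups")
    gidx = {g: i for i, g in enumerate(labels)}
    time = df["time_months"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    gcode = df["group"].map(gidx).to_numpy()

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        n_g = np.bincount(gcode[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gcode[(time == t) & (event == 1)], minlength=k).astype(float)
        d_t = d_g.sum()
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1.0)
            p = n_g / n_t
            V += c * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if diff.size == 0 or not np.any(np.abs(diff) > 0):
        chi2 = 0.0
    else:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p_value = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(
        statistic=chi2,
        df=k - 1,
        p_value=max(p_value, np.finfo(float).tiny),
        observed={g: float(O[gidx[g]]) for g in labels},
        expected={g: float(E[gidx[g]]) for g in labels},
    )


def cohort_report(
    calls: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    landmark_months: float = 60.0,
) -> dict:
    """Cohort composition and outcome summary.

    ``calls`` is a calls table (sample_id, call, qc_code, ...).  Subgroup
    frequencies are reported as percentages of classifiable samples (calls
    that are neither NC nor FAIL); QC dispositions are tallied over all
    samples.  With survival records, per-group landmark PFS (default
    5 years = 60 months) is read from the KM curves of classified samples.
    """
    report: dict = {"n_total": int(len(calls))}
    classified = calls[~calls["call"].isin(["NC", "FAIL"])]
    counts = classified["call"].value_counts().sort_index()
    n_class = int(len(classified))
    report["n_classified"] = n_class
    report["subgroup_counts"] = counts.to_dict()
    report["subgroup_percent"] = {
        g: 100.0 * c / n_class for g, c in counts.items()
    } if n_class else {}
    if "qc_code" in calls:
        report["qc_dispositions"] = calls["qc_code"].value_counts().to_dict()
    if survival is not None and n_class:
        surv = survival.drop(columns=["group"], errors="ignore")
        merged = classified.merge(surv, on="sample_id", how="inner")
        merged = merged.rename(columns={"call": "group"})[
            ["time_months", "event", "group"]
        ]
        curves = km_estimate(merged)
        report["landmark_pfs"] = {
            g: est.survival_at(landmark_months) for g, est in curves.items()
        }
    return report
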