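"""Kaplan-Meier estimation, k-sample log-rank / Gehan-Wilcoxon tests, and
event-frequency tables by methylation subgroup or diagnosis.

The k-sample test follows the weighted (O - E) construction: at each
distinct event time the expected events and the multivariate hypergeometric
covariance are accumulated per group with weight 1 (log-rank) or weight
equal to the total number at risk (Gehan-Breslow, emphasizing early
differences); the chi-square statistic uses a generalized inverse of the
covariance of the first k-1 groups and has k-1 degrees of freedom.
Censoring times tied with an event time count as at-risk at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

TESTS = ("logrank", "gehan")


@dataclass
class KMEstimate:
    table: pd.DataFrame  # time, at_risk, events, censored, survival

    def survival_at(self, t: float) -> float:
        """Product-limit S(t); step function, right-continuous."""
        tab = self.table[self.table["time"] <= t]
        if tab.empty:
            return 1.0
        return float(tab["survival"].iloc[-1])


@dataclass
class SurvivalTestResult:
    test: str
    chi_square: float
    df: int
    p_value: float
    group_sizes: dict
    observed: dict
    expected: dict
    weighted_diff: dict  # per-group sum of w*(O-E) over event times


def _check_times(times: np.ndarray) -> None:
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    _check_times(times)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev = kmf.event_table
    if not np.any(times == 0):  # drop lifelines' synthetic t=0 row
        ev = ev[ev.index > 0]
    grid = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    tab = pd.DataFrame({
        "time": grid,
        "at_risk": ev["at_risk"].to_numpy(),
        "events": ev["observed"].to_numpy(),
        "censored": ev["censored"].to_numpy(),
        "survival": surv,
    }).reset_index(drop=True)
    return KMEstimate(tab)


def k_sample_test(times, events, groups, test: str = "logrank"
                  ) -> SurvivalTestResult:
    """Weighted k-sample test of equal survival curves."""
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    _check_times(times)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 non-empty groups")
    gidx = np.searchsorted(labels, groups)

    event_times = np.unique(times[events])
    U = np.zeros(k)
    V = np.zeros((k, k))
    observed = np.zeros(k)
    expected = np.zeros(k)
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int((events & (times == t)).sum())
        if n <= 0 or d == 0:
            continue
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        o_g = np.bincount(gidx[events & (times == t)], minlength=k).astype(float)
        e_g = d * n_g / n
        w = float(n) if test == "gehan" else 1.0
        U += w * (o_g - e_g)
        observed += o_g
        expected += e_g
        if n > 1:
            frac = n_g / n
            cov_t = (d * (n - d) / (n - 1)) * (np.diag(frac) - np.outer(frac, frac))
            V += w * w * cov_t
    # drop one group; the remaining covariance may still be singular with
    # degenerate data, hence the generalized inverse
    u = U[:-1]
    v = V[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(v) @ u) if u.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return SurvivalTestResult(
        test=test, chi_square=chi2, df=df, p_value=p,
        group_sizes={str(g): int((groups == g).sum()) for g in labels},
        observed={str(g): float(observed[i]) for i, g in enumerate(labels)},
        expected={str(g): float(expected[i]) for i, g in enumerate(labels)},
        weighted_diff={str(g): float(U[i]) for i, g in enumerate(labels)},
    )


def event_frequency_table(metadata: pd.DataFrame, grouping: pd.Series
                          ) -> pd.DataFrame:
    """Per-group death and recurrence frequencies in percent (one decimal)."""
    grouping = grouping.reindex(metadata.index)
    rows = []
    for g in pd.unique(grouping.dropna()):
        sub = metadata[grouping == g]
        n = len(sub)
        death = sub["death_event"].astype("boolean")
        rec = sub["recurrence_event"].astype("boolean")
        rows.append({
            "group": g,
            "n": n,
            "deaths": int(death.sum()),
            "death_pct": round(100.0 * float(death.mean()), 1) if n else np.nan,
            "recurrences": int(rec.sum()),
            "recurrence_pct": round(100.0 * float(rec.mean()), 1) if n else np.nan,
        })
    return pd.DataFrame(rows)
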