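"""Expression-dichotomized survival analysis.

Kaplan-Meier product-limit curves and the two-group log-rank test, with
Benjamini-Hochberg adjustment for multi-candidate reporting. Patients are
split into high/low expression groups by the median (default) or by symmetric
quantiles (top q vs bottom q, middle unassigned). At tied times, events are
processed before censorings (standard convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["dichotomize", "km_curve", "logrank_test", "bh_adjust", "LogRankResult"]


def dichotomize(expression: pd.Series, rule="median") -> pd.Series:
    """High/low group labels from per-sample expression.

    rule="median": high = strictly above the median, low = the rest.
    rule=("quantile", q) or "q:<q>": high = top q fraction, low = bottom q
    fraction (floor(n*q) each, ties broken by sample id), middle unassigned
    (NaN).
    """
    expression = pd.Series(expression)
    if len(expression) < 2:
        raise ValueError("need at least 2 samples")
    if isinstance(rule, str) and rule.startswith("q:"):
        rule = ("quantile", float(rule[2:]))

    if rule == "median":
        if expression.nunique() == 1:
            raise ValueError("degenerate split: constant expression vector")
        med = expression.median()
        labels = np.where(expression > med, "high", "low")
        return pd.Series(labels, index=expression.index, name="group")

    kind, q = rule
    if kind != "quantile":
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    if not 0.0 < q < 0.5:
        raise ValueError("quantile q must be in (0, 0.5)")
    k = int(np.floor(len(expression) * q))
    if k < 1:
        raise ValueError("quantile split leaves an empty group")
    order = sorted(expression.index, key=lambda s: (-expression[s], str(s)))
    labels = pd.Series(np.nan, index=expression.index, dtype=object, name="group")
    labels[order[:k]] = "high"
    order_low = sorted(expression.index, key=lambda s: (expression[s], str(s)))
    labels[order_low[:k]] = "low"
    return labels


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time: time, n_at_risk, n_events,
    survival (the step value immediately after that time). S(0) = 1 and the
    curve drops only at event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    order = np.lexsort((1 - events, times))  # events before censorings at ties
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        d = 0
        at_risk = n - i
        j = i
        while j < n and times[j] == t:
            d += events[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, s))
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict  # group -> observed events
    expected: dict  # group -> expected events under H0


def logrank_test(table: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test on a table with time/event/group columns.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; the statistic is
    (sum O - sum E)^2 / sum V, referred to chi-square with 1 df.
    """
    groups = pd.unique(table["group"].dropna())
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {list(groups)}")
    g1, g2 = sorted(map(str, groups))
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    in1 = (table["group"].astype(str) == g1).to_numpy()

    if e.sum() == 0:
        warnings.warn("no events observed; log-rank p set to 1")
        return LogRankResult(0.0, 1, 1.0, {g1: 0, g2: 0}, {g1: 0.0, g2: 0.0})

    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    exp1 = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & in1).sum())
        e1 = d * n1 / n_tot
        o_minus_e += d1 - e1
        exp1 += e1
        if n_tot > 1:
            var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    obs1 = int(e[in1].sum())
    obs2 = int(e[~in1].sum())
    total_events = obs1 + obs2
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        float(chi2),
        1,
        max(p, np.finfo(float).tiny),
        {g1: obs1, g2: obs2},
        {g1: float(exp1), g2: float(total_events - exp1)},
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
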