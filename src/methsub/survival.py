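"""Kaplan-Meier curves per subtype and the g-group log-rank test.

Estimation and testing are delegated to lifelines; this module adds the
pipeline's conventions: observations censored at t=0 carry no
information and are dropped with a warning, and the comparison is
returned as per-group step functions plus the chi-square summary with
df = groups - 1. Ties are handled jointly through the hypergeometric
mean/variance of the standard log-rank statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .types import KMCurve, SurvivalComparison

__all__ = ["km_curve", "logrank"]


def _clean(times, events, groups=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    drop = (times == 0) & (events == 0)
    if np.any(drop):
        warnings.warn(f"dropping {int(drop.sum())} observation(s) censored at t=0",
                      stacklevel=3)
        keep = ~drop
        times, events = times[keep], events[keep]
        if groups is not None:
            groups = np.asarray(groups)[keep]
    if times.size == 0:
        raise ValueError("no informative observations after dropping t=0 censorings")
    return (times, events) if groups is None else (times, events, groups)


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate, reported at distinct event times."""
    times, events = _clean(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return KMCurve(times=np.array([]), survival=np.array([]), n=times.size)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(times=event_times, survival=surv, n=times.size)


def logrank(times, events, groups) -> SurvivalComparison:
    """g-group log-rank chi-square test plus per-group KM curves."""
    times, events, groups = _clean(times, events, np.asarray(groups))
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    curves = {}
    for g in uniq:
        m = groups == g
        curves[g] = km_curve(times[m], events[m])
    return SurvivalComparison(curves=curves, chi2=float(res.test_statistic),
                              df=int(uniq.size - 1), p=float(res.p_value))
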