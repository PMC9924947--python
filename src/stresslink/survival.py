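"""Survival-analysis primitives for lifespan and stress assays.

Worm survival assays produce right-censored time-to-event data: each animal
is followed until death (event = 1) or until it is removed from the assay
without an observed death, e.g. internal hatching or vulval extrusion
(event = 0).  This module provides the product-limit (Kaplan-Meier)
estimator, restricted-mean survival, fixed-time survival fractions, the
two-sample log-rank (Mantel-Cox) and Gehan-Breslow-Wilcoxon tests, one-way
ANOVA with Dunnett's many-to-one comparison, and Student's/Welch's t-test.

Conventions
-----------
* Animals censored exactly at an event time are counted as at risk at that
  time and removed afterwards (right-continuous convention).
* Tied death times use the standard hypergeometric variance term.
* All two-sample tests are symmetric in group order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time
from scipy import stats


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal's observation in one assay arm of one strain."""

    strain: str
    assay: str
    replicate: str
    time: float
    event: int  # 1 = death observed, 0 = censored
    control_group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple = ()
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _split(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValueError("no survival records supplied")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Censored-only input yields the constant curve S = 1 (no event times).
    """
    times, events = _split(records)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times, at_risk, deaths, surv = [], [], [], []
    s = 1.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        r = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / r
        event_times.append(t)
        at_risk.append(r)
        deaths.append(d)
        surv.append(s)
    return SurvivalCurve(
        times=np.array(event_times),
        at_risk=np.array(at_risk),
        deaths=np.array(deaths),
        survival=np.array(surv),
    )


def mean_survival(records: Sequence[SurvivalRecord]) -> float:
    """Mean survival time.

    Without censoring this is the arithmetic mean of death times.  With
    censoring it is the restricted mean: the area under the Kaplan-Meier
    curve up to the largest observed time.
    """
    times, events = _split(records)
    if events.all():
        return float(times.mean())
    kmf = KaplanMeierFitter().fit(times, events)
    return float(restricted_mean_survival_time(kmf, t=float(times.max())))


def fraction_alive(records: Sequence[SurvivalRecord], t: float) -> float:
    """Proportion of animals surviving past time ``t``.

    Animals censored at or before ``t`` carry no information about survival
    past ``t`` and are excluded from the denominator.
    """
    if t < 0:
        raise ValueError("time point must be >= 0")
    times, events = _split(records)
    alive = int(np.sum(times > t))
    censored_before = int(np.sum((times <= t) & (events == 0)))
    denom = len(times) - censored_before
    if denom == 0:
        raise ValueError(f"no animals remain under observation at t={t}")
    return alive / denom


def _two_sample(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    weightings: str | None,
    name: str,
) -> TestResult:
    ta, ea = _split(group_a)
    tb, eb = _split(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no deaths observed in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb,
                      weightings=weightings)
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        test_name=name,
        n_per_group=(len(ta), len(tb)),
        df=1,
    )


def logrank_test(group_a, group_b) -> TestResult:
    """Mantel-Cox log-rank test; chi-square statistic on 1 df."""
    return _two_sample(group_a, group_b, None, "logrank")


def gehan_wilcoxon_test(group_a, group_b) -> TestResult:
    """Gehan-Breslow-Wilcoxon test.

    A weighted log-rank test with weight equal to the total number at risk
    at each event time, emphasising early survival differences.
    """
    return _two_sample(group_a, group_b, "wilcoxon", "gehan-breslow-wilcoxon")


# many-to-one comparisons -------------------------------------------------

_DUNNETT_SEED = 714025  # fixed so adjusted p-values are reproducible


@dataclass
class DunnettResult:
    f_statistic: float
    anova_p: float
    adjusted_p: np.ndarray = field(default_factory=lambda: np.array([]))
    statistics: np.ndarray = field(default_factory=lambda: np.array([]))


def anova_dunnett(control: Sequence[float],
                  groups: Sequence[Sequence[float]]) -> DunnettResult:
    """One-way ANOVA plus Dunnett's many-to-one comparison against control.

    Each treatment group is compared with the shared control; adjusted
    two-sided p-values come from the equicorrelated multivariate-t
    distribution (randomised integration with a fixed internal seed).
    Assumes homogeneous variances across groups.
    """
    control = np.asarray(control, dtype=float)
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(control) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    f_stat, anova_p = stats.f_oneway(control, *arrs)
    dr = stats.dunnett(*arrs, control=control,
                       random_state=np.random.default_rng(_DUNNETT_SEED))
    return DunnettResult(
        f_statistic=float(f_stat),
        anova_p=float(anova_p),
        adjusted_p=np.asarray(dr.pvalue, dtype=float),
        statistics=np.asarray(dr.statistic, dtype=float),
    )


def students_t(group_a: Sequence[float], group_b: Sequence[float],
               welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test (pooled variance, or Welch if flagged)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return TestResult(0.0, 1.0, "t-test", (len(a), len(b)))
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    name = "welch-t" if welch else "t-test"
    return TestResult(float(t), float(p), name, (len(a), len(b)))
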