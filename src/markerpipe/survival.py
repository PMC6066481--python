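"""Nonparametric time-to-event estimation and two-sample tests.

Implements the estimators used throughout the validation stack:

* Kaplan–Meier product-limit estimate with Greenwood variance,
* the two-sample log-rank test (hypergeometric variance),
* the Aalen–Johansen estimator of cause-specific cumulative incidence with
  the counting-process (Aalen/Delta-method) variance,
* Gray's test for equality of subdistribution hazards of one cause,
  with an optional permutation reference.

Conventions
-----------
Times are non-negative offsets from the chosen origin.  At tied times,
events are ranked before censorings: a patient censored at an event time is
still in the risk set for that event.  All p-values are two-sided from the
chi-square reference distribution.

Causes are coded ``0`` = censored, ``1`` = relapse, ``2`` = death without
relapse (additional positive integer codes are accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateGroupsError,
    InvalidInputError,
    NoEventsError,
)

__all__ = [
    "SurvEstimate",
    "CifEstimate",
    "TwoSampleTest",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cuminc_estimate",
    "gray_test",
]


@dataclass
class SurvEstimate:
    """Kaplan–Meier step function on the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray          # Greenwood
    at_risk: np.ndarray
    n_events: np.ndarray
    max_time: float               # last observed follow-up (event or censor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "variance": self.variance,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class CifEstimate:
    """Aalen–Johansen cumulative incidence for one cause."""

    cause: int
    event_times: np.ndarray
    cif: np.ndarray
    variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "cif": self.cif, "variance": self.variance}
        )


@dataclass
class TwoSampleTest:
    statistic: float
    df: int
    p_value: float
    method: str = ""
    details: dict = field(default_factory=dict)


def _validate_times(times, events=None):
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise InvalidInputError("times must be a non-empty 1-d array")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise InvalidInputError("times must be finite and >= 0")
    if events is not None:
        events = np.asarray(events)
        if events.shape != times.shape:
            raise InvalidInputError("times and events must be aligned")
        events = events.astype(int)
        if not np.isin(events, (0, 1)).all():
            raise InvalidInputError("events must be 0/1")
        return times, events
    return times


def km_estimate(times, events) -> SurvEstimate:
    """Product-limit estimate of the survival function.

    Parameters
    ----------
    times : array of follow-up times (>= 0).
    events : 0/1 array, 1 = event observed, 0 = right-censored.
    """
    times, events = _validate_times(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return SurvEstimate(
            event_times=np.empty(0),
            survival=np.empty(0),
            variance=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            max_time=float(times.max()),
        )
    # at risk at t = number with T >= t; events before censorings at ties
    order = np.sort(times)
    n = times.size
    at_risk = n - np.searchsorted(order, event_times, side="left")
    ev_sorted = np.sort(times[events == 1])
    left = np.searchsorted(ev_sorted, event_times, side="left")
    right = np.searchsorted(ev_sorted, event_times, side="right")
    d = right - left
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        var = surv**2 * np.cumsum(gw_terms)
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 tail: variance 0 by convention
    return SurvEstimate(
        event_times=event_times,
        survival=surv,
        variance=var,
        at_risk=at_risk.astype(int),
        n_events=d.astype(int),
        max_time=float(times.max()),
    )


def survival_at(est: SurvEstimate, t: float, return_flag: bool = False):
    """Right-continuous read-off of the KM step function at time ``t``.

    Beyond the last observed follow-up the last value is carried forward;
    with ``return_flag=True`` the result is ``(value, extrapolated)`` so
    callers can tell a read-off from an extrapolation.
    """
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    extrapolated = t > est.max_time
    if est.event_times.size == 0:
        value = 1.0
    else:
        idx = np.searchsorted(est.event_times, t, side="right") - 1
        value = 1.0 if idx < 0 else float(est.survival[idx])
    return (value, extrapolated) if return_flag else value


def logrank_test(times, events, group) -> TwoSampleTest:
    """Two-sample log-rank test (1 df, chi-square reference).

    ``group`` is a binary indicator; the test is invariant to which level
    is labelled 1.
    """
    times, events = _validate_times(times, events)
    group = np.asarray(group).astype(int)
    if group.shape != times.shape:
        raise InvalidInputError("group must be aligned with times")
    if len(np.unique(group)) < 2:
        raise DegenerateGroupsError("both groups must be non-empty")

    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return TwoSampleTest(0.0, 1, 1.0, method="logrank")

    order_all = np.sort(times)
    order_1 = np.sort(times[group == 1])
    ev_all = np.sort(times[events == 1])
    ev_1 = np.sort(times[(events == 1) & (group == 1)])

    n_at = times.size - np.searchsorted(order_all, event_times, side="left")
    n1_at = order_1.size - np.searchsorted(order_1, event_times, side="left")
    d = np.searchsorted(ev_all, event_times, side="right") - np.searchsorted(
        ev_all, event_times, side="left"
    )
    d1 = np.searchsorted(ev_1, event_times, side="right") - np.searchsorted(
        ev_1, event_times, side="left"
    )

    p1 = n1_at / n_at
    expected = d * p1
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(
            n_at > 1, d * p1 * (1 - p1) * (n_at - d) / (n_at - 1), 0.0
        )
    observed_minus_expected = (d1 - expected).sum()
    var = v.sum()
    if var <= 0:
        return TwoSampleTest(0.0, 1, 1.0, method="logrank")
    chi2 = observed_minus_expected**2 / var
    p = float(stats.chi2.sf(chi2, 1))
    return TwoSampleTest(float(chi2), 1, p, method="logrank")


def _validate_causes(times, causes):
    times = _validate_times(times)
    causes = np.asarray(causes)
    if causes.shape != times.shape:
        raise InvalidInputError("times and causes must be aligned")
    causes = causes.astype(int)
    if np.any(causes < 0):
        raise InvalidInputError(
            "unknown cause code: causes are 0 (censored) or positive integers"
        )
    return times, causes


def cuminc_estimate(times, causes) -> list[CifEstimate]:
    """Aalen–Johansen cumulative incidence per cause.

    Returns one :class:`CifEstimate` per positive cause code present, each
    tabulated on the pooled distinct event times (all causes).  The variance
    is the counting-process (delta-method) estimator; with a single cause it
    reduces to Greenwood's formula for ``1 - KM``.
    """
    times, causes = _validate_causes(times, causes)
    cause_codes = sorted(int(c) for c in np.unique(causes) if c > 0)
    any_event = (causes > 0).astype(int)
    event_times = np.unique(times[any_event == 1])
    if event_times.size == 0:
        return [
            CifEstimate(c, np.empty(0), np.empty(0), np.empty(0)) for c in cause_codes
        ]

    order_all = np.sort(times)
    n_at = times.size - np.searchsorted(order_all, event_times, side="left")
    ev_all = np.sort(times[any_event == 1])
    d_all = np.searchsorted(ev_all, event_times, side="right") - np.searchsorted(
        ev_all, event_times, side="left"
    )
    # overall event-free KM, S(t-) via lagged product
    frac = 1.0 - d_all / n_at
    s_post = np.cumprod(frac)
    s_pre = np.concatenate(([1.0], s_post[:-1]))

    out = []
    for c in cause_codes:
        ev_c = np.sort(times[causes == c])
        d_c = np.searchsorted(ev_c, event_times, side="right") - np.searchsorted(
            ev_c, event_times, side="left"
        )
        jumps = s_pre * d_c / n_at
        cif = np.cumsum(jumps)
        var = _cif_variance(event_times, n_at, d_all, d_c, s_pre, cif, jumps)
        out.append(CifEstimate(c, event_times.copy(), cif, var))
    return out


def _cif_variance(event_times, n_at, d_all, d_c, s_pre, cif, jumps):
    """Delta-method variance of the Aalen–Johansen CIF (Aalen form).

    Follows the standard counting-process decomposition: for target time t,

        Var(F(t)) = sum_{j: t_j <= t} [
            (F(t) - F(t_j))^2 d_j / (n_j (n_j - d_j))
            + S(t_j-)^2 (n_j - d_cj) d_cj / n_j^3
            - 2 (F(t) - F(t_j)) S(t_j-) d_cj / n_j^2 ]
    """
    m = event_times.size
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_at > d_all, d_all / (n_at * (n_at - d_all)), 0.0)
    b = s_pre**2 * (n_at - d_c) * d_c / n_at**3
    c = s_pre * d_c / n_at**2
    # cumulative sums let every target time t_k reuse the same per-time terms
    A = np.cumsum(a)
    A1 = np.cumsum(a * cif)
    A2 = np.cumsum(a * cif**2)
    B = np.cumsum(b)
    C = np.cumsum(c)
    C1 = np.cumsum(c * cif)
    var = (cif**2 * A - 2 * cif * A1 + A2) + B - 2 * (cif * C - C1)
    return np.maximum(var, 0.0)


def _censoring_km(times, causes):
    """KM of the censoring distribution G (censorings as 'events')."""
    return km_estimate(times, (causes == 0).astype(int))


def _km_left_values(times_sorted_events, surv, query):
    idx = np.searchsorted(times_sorted_events, query, side="left")
    ext = np.concatenate(([1.0], surv))
    return ext[idx]


def _gray_score(times, causes, group, cause, return_influence=False):
    """Score statistic of Gray's test (rho = 0) for two groups.

    Uses the Fine–Gray subdistribution risk set: a subject who failed from a
    competing cause before t remains 'at risk' with weight G(t-)/G(T_i-)
    where G is the censoring-survival estimate (pooled).
    """
    n = times.size
    z = (np.asarray(group).astype(int) == 1).astype(float)

    g_est = _censoring_km(times, causes)
    g_times = g_est.event_times
    g_surv = g_est.survival

    event_mask = causes == cause
    event_times = np.unique(times[event_mask])

    # weight of subject i at time t:
    #   1                      if T_i >= t
    #   G(t-)/G(T_i-)          if failed from another cause at T_i < t
    #   0                      if censored or failed from this cause before t
    comp_mask = (causes > 0) & (causes != cause)
    g_at_comp = _km_left_values(g_times, g_surv, times[comp_mask])

    u = 0.0
    info = 0.0
    # per-event-time bookkeeping for the influence-function variance
    contribs = np.zeros(n)
    g_at_t = _km_left_values(g_times, g_surv, event_times)

    idx_comp = np.where(comp_mask)[0]
    order_times = np.sort(times)
    order_times_z = np.sort(times[z == 1])

    # natural risk set counts (T_i >= t), overall and group-1
    nat = n - np.searchsorted(order_times, event_times, side="left")
    nat1 = order_times_z.size - np.searchsorted(order_times_z, event_times, side="left")

    # weighted contribution of prior competing-cause failures
    comp_t = times[comp_mask]
    comp_z = z[comp_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_g_comp = np.where(g_at_comp > 0, 1.0 / g_at_comp, 0.0)
    ordc = np.argsort(comp_t)
    comp_t_s = comp_t[ordc]
    wsum_s = np.cumsum(inv_g_comp[ordc])
    wsum1_s = np.cumsum((inv_g_comp * comp_z)[ordc])
    pos = np.searchsorted(comp_t_s, event_times, side="left")
    wsum = np.concatenate(([0.0], wsum_s))[pos]
    wsum1 = np.concatenate(([0.0], wsum1_s))[pos]

    R = nat + g_at_t * wsum
    R1 = nat1 + g_at_t * wsum1
    pbar = np.where(R > 0, R1 / R, 0.0)

    ev_c_sorted = np.sort(times[event_mask])
    d = np.searchsorted(ev_c_sorted, event_times, side="right") - np.searchsorted(
        ev_c_sorted, event_times, side="left"
    )
    ev1_sorted = np.sort(times[event_mask & (z == 1)])
    d1 = np.searchsorted(ev1_sorted, event_times, side="right") - np.searchsorted(
        ev1_sorted, event_times, side="left"
    )

    u = float((d1 - d * pbar).sum())
    if not return_influence:
        return u, None

    # influence contributions: for each subject i,
    #   eta_i = sum_j (z_i - pbar_j) [ dN_i(t_j) - w_i(t_j) dLambda_j ]
    dlam = np.where(R > 0, d / R, 0.0)
    # event part
    ev_idx = np.where(event_mask)[0]
    pos_ev = np.searchsorted(event_times, times[ev_idx])
    contribs[ev_idx] += z[ev_idx] - pbar[pos_ev]
    # at-risk part: subjects with T_i >= t_j contribute -(z_i - pbar_j) dlam_j
    term = (z[:, None] - pbar[None, :]) * dlam[None, :]
    at_risk_mask = times[:, None] >= event_times[None, :]
    contribs -= (term * at_risk_mask).sum(axis=1)
    # competing-cause weighted part
    if idx_comp.size:
        w_comp = g_at_t[None, :] * inv_g_comp[:, None]  # (n_comp, n_times)
        later = event_times[None, :] > comp_t[:, None]
        term_c = (comp_z[:, None] - pbar[None, :]) * dlam[None, :] * w_comp * later
        contribs[idx_comp] -= term_c.sum(axis=1)
    return u, contribs


def gray_test(
    times,
    causes,
    group,
    cause_of_interest: int = 1,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> TwoSampleTest:
    """Gray's two-sample test for equality of subdistribution hazards.

    The statistic is the Fine–Gray weighted score; its variance is estimated
    from per-subject influence contributions, and the p-value is two-sided
    from the chi-square(1) reference.  If ``n_permutations`` is given, the
    p-value is instead the group-label permutation tail probability of the
    score statistic (exact under exchangeability); the chi-square statistic
    is still reported.
    """
    times, causes = _validate_causes(times, causes)
    group = np.asarray(group).astype(int)
    if group.shape != times.shape:
        raise InvalidInputError("group must be aligned with times")
    if len(np.unique(group)) < 2:
        raise DegenerateGroupsError("both groups must be non-empty")
    if not np.any(causes == cause_of_interest):
        raise NoEventsError(f"no events of cause {cause_of_interest}")

    u, contribs = _gray_score(times, causes, group, cause_of_interest, True)
    var = float((contribs**2).sum())
    if var <= 0:
        return TwoSampleTest(0.0, 1, 1.0, method="gray")
    chi2 = u**2 / var
    p = float(stats.chi2.sf(chi2, 1))
    method = "gray"
    if n_permutations:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(group)
            u_p, _ = _gray_score(times, causes, perm, cause_of_interest, False)
            if abs(u_p) >= abs(u) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = "gray-permutation"
    return TwoSampleTest(float(chi2), 1, p, method=method, details={"score": u})
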