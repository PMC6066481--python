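"""Endpoint construction, contingency tables, and cohort summaries.

Time origins follow the standard reporting conventions for AML trials:
overall survival (OS) runs from diagnosis, relapse-free survival (RFS) and
cumulative incidence of relapse (CIR) from the date of remission, and the
transplant-subgroup analyses from the transplant date.  Alive patients are
right-censored at last follow-up.  Competing-risk causes are coded
1 = relapse and 2 = death without relapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ClinicalCohort
from .errors import (
    DataIntegrityError,
    InvalidInputError,
    UndefinedTestError,
)

__all__ = [
    "EndpointSet",
    "ContingencyTable",
    "build_endpoints",
    "fisher_exact",
    "summarize_cohort",
    "survivors_at_horizon",
]

logger = logging.getLogger(__name__)


@dataclass
class EndpointSet:
    """Per-patient endpoint times from one origin.

    ``os`` covers every patient; ``rfs``/``cir`` only patients who achieved
    CR (or, for the transplant origin, only transplanted patients).
    """

    origin: str
    os: pd.DataFrame    # index patient_id; columns time, event
    rfs: pd.DataFrame   # index patient_id; columns time, event
    cir: pd.DataFrame   # index patient_id; columns time, cause
    n_excluded: int     # patients lacking the origin event


def build_endpoints(cohort: ClinicalCohort, origin: str = "diagnosis") -> EndpointSet:
    """Compute OS / RFS / CIR times from the chosen origin.

    origin: 'diagnosis', 'cr' or 'transplant'.  With 'cr' or 'transplant',
    patients lacking that event are excluded (count logged and returned).
    RFS events are relapse or death, whichever first; CIR causes are
    1 = relapse, 2 = death without relapse, 0 = censored.
    """
    d = cohort.data.set_index("patient_id")
    bad = d.index[
        d["relapse_day"].notna()
        & (d["cr_day"].isna() | (d["relapse_day"] < d["cr_day"]))
    ]
    if len(bad):
        raise DataIntegrityError("relapse before CR", patient_ids=bad)

    if origin == "diagnosis":
        origin_day = pd.Series(0.0, index=d.index)
    elif origin == "cr":
        origin_day = d["cr_day"]
    elif origin == "transplant":
        origin_day = d["hsct_day"]
    else:
        raise InvalidInputError(f"unknown origin {origin!r}")

    keep = origin_day.notna()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("build_endpoints(origin=%s): excluded %d patients", origin, n_excluded)
    d = d[keep]
    origin_day = origin_day[keep]

    dead = d["death_day"].notna()
    os_time = d["last_followup_day"] - origin_day
    os_df = pd.DataFrame({"time": os_time, "event": dead.astype(int)})

    # RFS/CIR need the remission event (and start no earlier than the origin)
    has_cr = d["cr_day"].notna()
    if origin in ("diagnosis", "cr"):
        sub = d[has_cr]
        start = sub["cr_day"]
    else:  # transplant origin: post-transplant relapse/death
        sub = d
        start = origin_day[sub.index]
    relapse = sub["relapse_day"]
    end = sub["last_followup_day"]
    rel_event = relapse.notna() & (relapse >= start)
    first_fail = pd.concat(
        [relapse.where(rel_event), sub["death_day"]], axis=1
    ).min(axis=1)
    failed = first_fail.notna() & (first_fail >= start)
    rfs_time = (first_fail.where(failed, end) - start).clip(lower=0.0)
    rfs_df = pd.DataFrame(
        {"time": rfs_time, "event": failed.astype(int)}, index=sub.index
    )
    cause = np.where(
        rel_event & failed, 1, np.where(sub["death_day"].notna() & failed, 2, 0)
    )
    cir_df = pd.DataFrame({"time": rfs_time, "cause": cause}, index=sub.index)
    return EndpointSet(origin, os_df, rfs_df, cir_df, n_excluded)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sidedness by the minimum-likelihood rule: the p-value sums the
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise InvalidInputError("fisher_exact expects a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise InvalidInputError("counts must be non-negative integers")
        table = table.astype(int)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise UndefinedTestError("empty margin: Fisher's test undefined")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _fisher_2xk(table: np.ndarray, n_mc: int = 200_000, seed: int = 0) -> float:
    """Exact-conditional p for a 2xk table by Monte-Carlo over fixed margins.

    The test statistic is the table's conditional probability (smaller or
    equal probability counts toward the tail), matching the 2x2 two-sided
    rule.
    """
    if table.shape[1] == 2:
        return fisher_exact(table)
    row = table.sum(axis=1)
    if row.min() == 0 or table.sum(axis=0).min() == 0:
        raise UndefinedTestError("empty margin: Fisher's test undefined")
    rng = np.random.default_rng(seed)
    logp_obs = _log_table_prob(table)
    # sample tables with fixed margins by permuting group labels
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    n1 = row[0]
    count = 0
    k = table.shape[1]
    for _ in range(n_mc):
        rng.shuffle(cols)
        top = np.bincount(cols[:n1], minlength=k)
        t = np.vstack([top, table.sum(axis=0) - top])
        if _log_table_prob(t) <= logp_obs + 1e-12:
            count += 1
    return (count + 1) / (n_mc + 1)


def _log_table_prob(table: np.ndarray) -> float:
    from scipy.special import gammaln

    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


@dataclass
class ContingencyTable:
    variable: str
    levels: list
    counts: pd.DataFrame        # index level, columns marker groups
    row_percent: pd.DataFrame   # 100 * count / level total, 1-dp reporting
    fisher_p: float | None

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy().astype(str)
        for lvl in self.counts.index:
            for g in self.counts.columns:
                out.loc[lvl, g] = (
                    f"{self.counts.loc[lvl, g]} ({self.row_percent.loc[lvl, g]:.1f})"
                )
        out["fisher_p"] = ""
        if self.fisher_p is not None and len(out):
            out.iloc[0, -1] = f"{self.fisher_p:.3g}"
        return out


def summarize_cohort(
    cohort: ClinicalCohort,
    marker_status=None,
    variables: list[str] | None = None,
    mc_seed: int = 0,
) -> dict[str, ContingencyTable]:
    """Association of marker status with categorical patient characteristics.

    Each variable yields a levels-by-marker-group table of counts and row
    percentages plus a Fisher p (exact for two levels, Monte-Carlo
    conditional-exact for more).  Continuous variables must be categorized
    upstream.  Row percentages are percentages of each variable level that
    fall in each marker group, matching the layout of cohort tables in
    clinical reports.
    """
    d = cohort.data
    status = (
        pd.Series(marker_status, index=d.index)
        if marker_status is not None
        else d["marker_status"]
    )
    status = status.replace("", np.nan)
    variables = variables or [
        "cytogenetic_risk",
        "npm1",
        "flt3_itd",
        "cr_achieved",
    ]
    out = {}
    for var in variables:
        if var not in d.columns:
            logger.warning("variable %s missing; skipped", var)
            continue
        sub = pd.DataFrame({"level": d[var], "group": status}).dropna()
        if sub.empty:
            logger.warning("variable %s all-missing; skipped", var)
            continue
        counts = (
            sub.groupby(["level", "group"], observed=True)
            .size()
            .unstack(fill_value=0)
            .sort_index()
        )
        totals = counts.sum(axis=1)
        pct = 100.0 * counts.div(totals, axis=0)
        p = None
        if counts.shape == (2, 2) and counts.to_numpy().sum() > 0:
            try:
                p = fisher_exact(counts.to_numpy())
            except UndefinedTestError:
                p = None
        elif counts.shape[0] >= 2 and counts.shape[1] == 2:
            try:
                p = _fisher_2xk(counts.to_numpy().T, seed=mc_seed)
            except UndefinedTestError:
                p = None
        out[var] = ContingencyTable(var, list(counts.index), counts, pct, p)
    return out


def survivors_at_horizon(
    cohort: ClinicalCohort,
    horizon_days: float,
    marker_status=None,
) -> pd.DataFrame:
    """Patients alive at the horizon, among those with adequate follow-up.

    A patient is eligible when their potential follow-up reaches the
    horizon: they died (at any time) or were followed at least
    ``horizon_days``.  Returns counts and percentages by marker group.
    """
    if horizon_days <= 0:
        raise InvalidInputError("horizon must be > 0")
    d = cohort.data
    status = (
        pd.Series(marker_status, index=d.index)
        if marker_status is not None
        else d["marker_status"]
    ).replace("", np.nan)
    dead = d["death_day"].notna()
    eligible = dead | (d["last_followup_day"] >= horizon_days)
    if not eligible.any():
        raise InvalidInputError("no patients with potential follow-up at horizon")
    alive_at = ~ (dead & (d["death_day"] <= horizon_days))
    sub = pd.DataFrame(
        {"group": status, "alive": alive_at & (d["last_followup_day"] >= horizon_days)}
    )[eligible].dropna(subset=["group"])
    g = sub.groupby("group")["alive"]
    out = pd.DataFrame(
        {"n_eligible": g.size(), "n_alive": g.sum().astype(int)}
    )
    out["percent_alive"] = 100.0 * out["n_alive"] / out["n_eligible"]
    return out
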