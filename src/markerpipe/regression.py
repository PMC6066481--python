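"""Multivariable outcome models.

The validation stack fits, per endpoint:

* logistic regression for failure of complete remission (the marker's
  adjusted odds ratio > 1 means a higher probability of refractory
  disease),
* Cox proportional hazards for OS and RFS, with allogeneic transplant as a
  time-dependent covariate (a patient's HSCT indicator switches 0 -> 1 at
  the transplant date within their follow-up),
* the Lunn–McNeil stacked-data extension for competing risks, yielding
  cause-specific hazard ratios for relapse and for death without relapse,
* a flexible time-dependent check of the proportional-hazards assumption:
  each covariate is interacted with a restricted cubic spline of log time
  (3 knots) and tested against the PH model by likelihood ratio.

Covariate conventions follow the adjustment set used in AML prognostic
studies: age with linear plus quadratic terms (centered before squaring;
the two coefficients are interpreted jointly), WBC either as the
categories <50 / 50-99 / >=100 x10^9/L or as log WBC, cytogenetic risk
with favorable as reference, NPM1 and FLT3-ITD with their interaction.
Wald confidence intervals are reported throughout; ties use the Efron
approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxResult, cox_newton, episode_split
from .cohort import ClinicalCohort
from .errors import (
    ConvergenceError,
    InvalidInputError,
    NoEventsError,
    SeparationError,
)
from .report import build_endpoints

__all__ = [
    "ModelSpec",
    "ModelFit",
    "logistic_fit",
    "cox_fit",
    "ph_test",
    "lunn_mcneil_fit",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("cr", "os", "rfs", "cir-relapse", "cir-death")

# terms understood by the design-matrix builder
TERMS = (
    "marker",
    "age",                    # expands to centered linear + quadratic
    "wbc_category",
    "wbc_log",
    "cytogenetic_risk",
    "npm1",
    "flt3_itd",
    "npm1_flt3_interaction",
    "tp53",
    "runx1",
    "asxl1",
    "bicebpa",
    "hsct_td",
)


@dataclass(frozen=True)
class ModelSpec:
    """Outcome plus ordered covariate terms."""

    outcome: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise InvalidInputError(f"unknown outcome {self.outcome!r}")
        unknown = [t for t in self.terms if t not in TERMS]
        if unknown:
            raise InvalidInputError(f"unknown terms {unknown}")
        if self.outcome == "cr" and "hsct_td" in self.terms:
            raise InvalidInputError(
                "transplant is a time-dependent covariate and cannot enter the "
                "CR (induction response) model"
            )
        if "npm1_flt3_interaction" in self.terms and not (
            "npm1" in self.terms and "flt3_itd" in self.terms
        ):
            raise InvalidInputError("interaction requires npm1 and flt3_itd terms")
        if "wbc_category" in self.terms and "wbc_log" in self.terms:
            raise InvalidInputError("choose one WBC encoding")

    @classmethod
    def standard(cls, outcome: str, wbc: str = "wbc_category") -> "ModelSpec":
        """The canonical adjustment set: marker + age + WBC + cytogenetic
        risk + NPM1 + FLT3-ITD + their interaction (+ time-dependent HSCT
        for time-to-event outcomes)."""
        terms = [
            "marker",
            "age",
            wbc,
            "cytogenetic_risk",
            "npm1",
            "flt3_itd",
            "npm1_flt3_interaction",
        ]
        if outcome != "cr":
            terms.append("hsct_td")
        return cls(outcome, tuple(terms))

    @classmethod
    def marker_only(cls, outcome: str) -> "ModelSpec":
        return cls(outcome, ("marker",))


@dataclass
class ModelFit:
    """One fitted regression: per-term estimates plus fit metadata."""

    outcome: str
    table: pd.DataFrame  # term, coef, se, ratio, ci_low, ci_high, p
    loglik: float
    n_used: int
    n_events: int
    converged: bool
    ratio_label: str = "HR"
    joint_tests: dict = field(default_factory=dict)
    n_dropped: int = 0

    def ratio(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "ratio"])


def _wald_table(names, beta, cov, ratio_label):
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        return _wald_frame(names, beta, se, p)


def _wald_frame(names, beta, se, p):
    return pd.DataFrame(
        {
            "term": names,
            "coef": beta,
            "se": se,
            "ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "p": p,
        }
    )


def _joint_wald(names, beta, cov, prefix):
    idx = [i for i, n in enumerate(names) if n.startswith(prefix)]
    if not idx:
        return None
    b = beta[idx]
    v = np.asarray(cov)[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(v, b))
    except np.linalg.LinAlgError:
        return None
    return float(stats.chi2.sf(chi2, len(idx)))


def build_design(cohort: ClinicalCohort, spec: ModelSpec) -> pd.DataFrame:
    """Expand model terms into numeric columns; complete cases only.

    Returns a DataFrame indexed by patient_id with one column per design
    term (age centered and scaled per decade; dummies against reference
    levels) and logs the number of rows dropped for missing covariates.
    """
    d = cohort.data.set_index("patient_id")
    cols = {}
    for term in spec.terms:
        if term == "marker":
            status = d["marker_status"].replace("", np.nan)
            cols["marker"] = status.map({"H+": 1.0, "H-": 0.0})
        elif term == "age":
            age_c = (d["age_years"] - d["age_years"].mean()) / 10.0
            cols["age_per_decade"] = age_c
            cols["age_per_decade_sq"] = age_c**2
        elif term == "wbc_category":
            cols["wbc_50_99"] = ((d["wbc"] >= 50) & (d["wbc"] < 100)).astype(float)
            cols["wbc_ge_100"] = (d["wbc"] >= 100).astype(float)
        elif term == "wbc_log":
            cols["wbc_log"] = np.log(d["wbc"].where(d["wbc"] > 0))
        elif term == "cytogenetic_risk":
            # favorable is the reference; patients with undetermined
            # cytogenetics are excluded from risk-adjusted models (they are
            # too few to support their own stratum and have no risk label)
            known = d["cytogenetic_risk"].isin(
                ("favorable", "intermediate", "adverse")
            )
            for level in ("intermediate", "adverse"):
                dummy = (d["cytogenetic_risk"] == level).astype(float)
                cols[f"cyto_{level}"] = dummy.where(known)
        elif term == "npm1_flt3_interaction":
            cols["npm1_x_flt3_itd"] = (
                d["npm1"].astype(float) * d["flt3_itd"].astype(float)
            )
        elif term in ("npm1", "flt3_itd", "tp53", "runx1", "asxl1", "bicebpa"):
            cols[term] = d[term].astype(float)
        elif term == "hsct_td":
            continue  # handled by the counting-process builder
    X = pd.DataFrame(cols, index=d.index)
    n0 = len(X)
    X = X.dropna()
    if len(X) < n0:
        logger.info("dropped %d incomplete cases", n0 - len(X))
    X.attrs["n_dropped"] = n0 - len(X)
    return X


def logistic_fit(cohort: ClinicalCohort, spec: ModelSpec) -> ModelFit:
    """Multivariable logistic model for failure of complete remission.

    The modeled event is *not* achieving CR, so the marker's adjusted odds
    ratio above 1 means a higher probability of refractory disease.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if spec.outcome != "cr":
        raise InvalidInputError("logistic_fit requires outcome='cr'")
    X = build_design(cohort, spec)
    d = cohort.data.set_index("patient_id").loc[X.index]
    y = 1 - d["cr_achieved"].astype(int)  # event = induction failure
    if y.nunique() < 2:
        raise InvalidInputError("outcome is constant")

    design = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    beta = res.params.to_numpy()
    if np.abs(beta).max() > 15:
        worst = design.columns[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"quasi-complete separation (|coef| diverging for {worst})",
            covariate=worst,
        )
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge")

    names = list(design.columns)
    table = _wald_table(names, beta, res.cov_params().to_numpy(), "OR")
    joint = {}
    p_age = _joint_wald(names, beta, res.cov_params().to_numpy(), "age_per_decade")
    if p_age is not None:
        joint["age"] = p_age
    return ModelFit(
        outcome="cr",
        table=table,
        loglik=float(res.llf),
        n_used=len(y),
        n_events=int(y.sum()),
        converged=True,
        ratio_label="OR",
        joint_tests=joint,
        n_dropped=X.attrs.get("n_dropped", 0),
    )


def _counting_process_data(cohort, spec, endpoints=None, outcome=None):
    """(start, stop, event, X, names) for a time-to-event outcome.

    Events recorded exactly at the origin are shifted forward by half a
    day so every row has positive duration.
    """
    outcome = outcome or spec.outcome
    origin = "cr" if outcome in ("rfs", "cir-relapse", "cir-death") else "diagnosis"
    eps = build_endpoints(cohort, origin=origin) if endpoints is None else endpoints
    if outcome == "os":
        tbl = eps.os
        time = tbl["time"].to_numpy(dtype=float)
        event = tbl["event"].to_numpy(dtype=int)
        index = tbl.index
    elif outcome == "rfs":
        tbl = eps.rfs
        time = tbl["time"].to_numpy(dtype=float)
        event = tbl["event"].to_numpy(dtype=int)
        index = tbl.index
    elif outcome in ("cir-relapse", "cir-death"):
        cause = 1 if outcome == "cir-relapse" else 2
        tbl = eps.cir
        time = tbl["time"].to_numpy(dtype=float)
        event = (tbl["cause"].to_numpy(dtype=int) == cause).astype(int)
        index = tbl.index
    else:
        raise InvalidInputError(f"not a time-to-event outcome: {outcome}")

    X = build_design(cohort, spec)
    keep = index.intersection(X.index)
    X = X.loc[keep]
    pos = index.get_indexer(keep)
    time = np.maximum(time[pos], 0.5)
    event = event[pos]

    d = cohort.data.set_index("patient_id").loc[keep]
    names = list(X.columns)
    Xm = X.to_numpy()
    n = len(keep)

    if "hsct_td" not in spec.terms:
        return (
            np.zeros(n),
            time,
            event,
            Xm,
            names,
            np.arange(n),
            X.attrs.get("n_dropped", 0),
        )

    origin_day = (
        d["cr_day"].to_numpy(dtype=float)
        if origin == "cr"
        else np.zeros(n)
    )
    hsct_rel = d["hsct_day"].to_numpy(dtype=float) - origin_day
    starts, stops, events_, rows, hvals = [], [], [], [], []
    for i in range(n):
        h = hsct_rel[i]
        if np.isfinite(h) and 0 < h < time[i]:
            starts += [0.0, h]
            stops += [h, time[i]]
            events_ += [0, event[i]]
            rows += [i, i]
            hvals += [0.0, 1.0]
        else:
            pre = bool(np.isfinite(h) and h <= 0)
            starts.append(0.0)
            stops.append(time[i])
            events_.append(event[i])
            rows.append(i)
            hvals.append(1.0 if pre else 0.0)
    rows = np.asarray(rows)
    Xfull = np.column_stack([Xm[rows], np.asarray(hvals)])
    return (
        np.asarray(starts),
        np.asarray(stops),
        np.asarray(events_, dtype=int),
        Xfull,
        names + ["hsct"],
        rows,
        X.attrs.get("n_dropped", 0),
    )


def _fit_to_modelfit(outcome, res: CoxResult, names, n_used, n_dropped) -> ModelFit:
    table = _wald_table(names, res.beta, res.cov, "HR")
    joint = {}
    p_age = _joint_wald(names, res.beta, res.cov, "age_per_decade")
    if p_age is not None:
        joint["age"] = p_age
    return ModelFit(
        outcome=outcome,
        table=table,
        loglik=res.loglik,
        n_used=n_used,
        n_events=res.n_events,
        converged=res.converged,
        ratio_label="HR",
        joint_tests=joint,
        n_dropped=n_dropped,
    )


def cox_fit(
    cohort: ClinicalCohort, spec: ModelSpec, endpoints=None
) -> ModelFit:
    """Cox proportional-hazards fit for OS or RFS (Efron ties, Wald CIs)."""
    if spec.outcome not in ("os", "rfs"):
        raise InvalidInputError("cox_fit handles outcomes 'os' and 'rfs'")
    start, stop, event, X, names, rows, n_dropped = _counting_process_data(
        cohort, spec, endpoints
    )
    if event.sum() == 0:
        raise NoEventsError("no events for Cox fit")
    res = cox_newton(X, start, stop, event)
    n_used = len(np.unique(rows))
    return _fit_to_modelfit(spec.outcome, res, names, n_used, n_dropped)


def lunn_mcneil_fit(
    cohort: ClinicalCohort, spec: ModelSpec, endpoints=None
) -> dict[int, ModelFit]:
    """Competing-risks Cox via data augmentation (Lunn–McNeil).

    The CR-patient data are duplicated into one stratum per cause; in the
    stratum for cause k the events of other causes count as censorings.
    Covariates are interacted with the stratum so each cause has its own
    coefficients, and a single stratified Cox fit returns cause-specific
    hazard ratios for relapse (cause 1) and death without relapse
    (cause 2).
    """
    spec_rel = ModelSpec("cir-relapse", spec.terms)
    start, stop, event_rel, X, names, rows, n_dropped = _counting_process_data(
        cohort, spec_rel, endpoints
    )
    # recover full cause codes on the expanded rows
    spec_dth = ModelSpec("cir-death", spec.terms)
    _, _, event_dth, _, _, _, _ = _counting_process_data(
        cohort, spec_dth, endpoints
    )

    causes_present = []
    for cause, ev in ((1, event_rel), (2, event_dth)):
        if ev.sum() == 0:
            logger.warning("cause %d has no events; omitted", cause)
        else:
            causes_present.append((cause, ev))
    if not causes_present:
        raise NoEventsError("no events of any cause")

    p = X.shape[1]
    k = len(causes_present)
    n_rows = start.size
    Xs = np.zeros((k * n_rows, k * p))
    starts = np.tile(start, k)
    stops = np.tile(stop, k)
    events = np.concatenate([ev for _, ev in causes_present])
    strata = np.repeat([c for c, _ in causes_present], n_rows)
    big_names = []
    for j, (cause, _) in enumerate(causes_present):
        Xs[j * n_rows : (j + 1) * n_rows, j * p : (j + 1) * p] = X
        big_names += [f"{nm}:cause{cause}" for nm in names]

    res = cox_newton(Xs, starts, stops, events, strata=strata)
    n_used = len(np.unique(rows))
    out = {}
    for j, (cause, ev) in enumerate(causes_present):
        sl = slice(j * p, (j + 1) * p)
        sub = CoxResult(
            beta=res.beta[sl],
            cov=res.cov[sl, sl],
            loglik=res.loglik,
            loglik_null=res.loglik_null,
            n_iter=res.n_iter,
            converged=res.converged,
            n_obs=n_rows,
            n_events=int(ev.sum()),
        )
        out[cause] = _fit_to_modelfit(
            "cir-relapse" if cause == 1 else "cir-death",
            sub,
            names,
            n_used,
            n_dropped,
        )
    return out


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline nonlinear basis (3 knots -> one column)."""
    k1, k2, k3 = knots

    def cube(v):
        return np.clip(v, 0, None) ** 3

    num = (
        cube(x - k1)
        - cube(x - k2) * (k3 - k1) / (k3 - k2)
        + cube(x - k3) * (k2 - k1) / (k3 - k2)
    )
    return num / (k3 - k1) ** 2


def ph_test(
    cohort: ClinicalCohort,
    spec: ModelSpec,
    covariates: list[str] | None = None,
    endpoints=None,
) -> dict[str, float]:
    """Flexible time-dependent check of proportional hazards.

    For each requested covariate the PH model is extended with the
    covariate interacted with [log t, rcs(log t)] (restricted cubic
    spline, 3 knots at the 10th/50th/90th percentiles of event times) and
    compared by likelihood-ratio test (2 df).  With fewer than 20 events
    the spline term is dropped and a linear-in-log-time interaction is
    used (1 df, logged).  Returns a p-value per covariate; small p means
    evidence against proportionality.
    """
    start, stop, event, X, names, rows, _ = _counting_process_data(
        cohort, spec, endpoints
    )
    if covariates is None:
        covariates = names
    missing = [c for c in covariates if c not in names]
    if missing:
        raise InvalidInputError(f"covariates not in the model: {missing}")

    ev_times = np.unique(stop[event == 1])
    base = cox_newton(X, start, stop, event)

    s_start, s_stop, s_event, s_X, _ = episode_split(start, stop, event, X, ev_times)
    logt = np.log(s_stop)
    use_spline = event.sum() >= 20
    if use_spline:
        knots = np.quantile(np.log(ev_times), [0.1, 0.5, 0.9])
        if np.unique(knots).size < 3:
            use_spline = False
    if use_spline:
        tv = np.column_stack([logt, _rcs_basis(logt, knots)])
    else:
        logger.info("ph_test: too few events for spline; linear-in-log-time")
        tv = logt[:, None]
    tv = tv - tv.mean(axis=0)

    # base model on split data has identical likelihood; refit for safety
    base_split = cox_newton(s_X, s_start, s_stop, s_event)
    if abs(base_split.loglik - base.loglik) > 1e-6 * max(1, abs(base.loglik)):
        logger.debug("episode-split likelihood drift: %g", base_split.loglik - base.loglik)

    out = {}
    for cov in covariates:
        j = names.index(cov)
        Xe = np.column_stack([s_X, tv * s_X[:, [j]]])
        try:
            ext = cox_newton(Xe, s_start, s_stop, s_event)
        except (SeparationError, ConvergenceError):
            out[cov] = np.nan
            continue
        lrt = 2 * (ext.loglik - base_split.loglik)
        out[cov] = float(stats.chi2.sf(max(lrt, 0.0), tv.shape[1]))
    return out
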