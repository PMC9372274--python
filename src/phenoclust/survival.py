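"""Survival analysis: Kaplan–Meier curves, log-rank tests and Cox regression.

Survival time runs from definitive surgery to death or right-censoring
(last revisit / last follow-up).  Cluster membership and phenotype term
flags enter Cox proportional-hazards models as covariates; variable
selection follows a prevalence screen (terms above 5% prevalence enter the
univariate screen; the multivariate model takes univariate-significant
variables plus clusters, demographics, surgery type, and terms above 25%
prevalence).

The Cox fit maximises the partial likelihood by Newton–Raphson with
Efron's tie correction (Breslow available), standard errors from the
inverse observed information, and Wald confidence intervals
``exp(coef ± 1.96·SE)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .clustering import ClusterAssignment
from .cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "build_survival_frame",
    "select_variables",
    "univariate_cox_screen",
    "multivariate_cox",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class KMCurve:
    """Product-limit survival estimate Ŝ(t) = Π_{t_i ≤ t} (1 − d_i/n_i)."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray  # n_i just before each event time
    events: np.ndarray  # d_i deaths at each event time
    survival: np.ndarray  # Ŝ(t_i) just after each event time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Ŝ(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with Ŝ ≤ 0.5 (inf if never reached)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan–Meier estimate of one group's survival function.

    Censorings tied with deaths at the same time are handled events-first
    (the censored subject is still in the risk set at that time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    event_times = death_rows.index.to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMCurve(
        times=event_times,
        at_risk=death_rows["at_risk"].to_numpy(dtype=int),
        events=death_rows["observed"].to_numpy(dtype=int),
        survival=surv,
        label=label,
    )


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square, df, p).

    Observed-minus-expected death counts over the pooled risk sets with
    hypergeometric variance; p from the chi-square upper tail with
    k−1 degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank needs at least two groups")
    if events.sum() == 0:
        raise ValueError("log-rank is undefined with zero events")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


@dataclass
class CoxResult:
    """Cox regression estimates: one row per covariate."""

    table: pd.DataFrame  # coef, se, hr, ci_low, ci_high, z, p
    model: str  # "univariate" | "multivariate"
    ties: str
    log_likelihood: float
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


class CoxConvergenceError(RuntimeError):
    pass


def _cox_loglik_derivs(beta, X, time, event, ties):
    """Log partial likelihood, gradient and observed information.

    One sweep over event times in decreasing order maintaining running
    risk-set sums; Efron's correction downweights tied deaths' own
    contribution within each tie group.
    """
    n, p = X.shape
    eta = X @ beta
    # clip to keep exp finite during aggressive Newton steps
    w = np.exp(np.clip(eta, -500, 500))
    order = np.argsort(-time, kind="stable")

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))

    i = 0
    m = len(order)
    while i < m:
        t = time[order[i]]
        j = i
        deaths = []
        while j < m and time[order[j]] == t:
            idx = order[j]
            xi = X[idx]
            S0 += w[idx]
            S1 += w[idx] * xi
            S2 += w[idx] * np.outer(xi, xi)
            if event[idx]:
                deaths.append(idx)
            j += 1
        if deaths:
            d = len(deaths)
            xd = X[deaths]
            wd = w[deaths]
            s0d = wd.sum()
            s1d = wd @ xd
            s2d = (wd[:, None] * xd).T @ xd
            ll += eta[deaths].sum()
            grad += xd.sum(axis=0)
            fracs = (
                np.arange(d) / d if ties == "efron" else np.zeros(d)
            )
            for frac in fracs:
                phi = S0 - frac * s0d
                psi1 = S1 - frac * s1d
                psi2 = S2 - frac * s2d
                ll -= np.log(phi)
                grad -= psi1 / phi
                info += psi2 / phi - np.outer(psi1, psi1) / phi**2
        i = j
    return ll, grad, info


def cox_fit(
    X,
    times,
    events,
    names: list[str] | None = None,
    ties: str = "efron",
    model: str = "univariate",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton–Raphson partial likelihood.

    Parameters
    ----------
    X
        (n, p) covariate matrix (no intercept — the baseline hazard
        absorbs it).
    times, events
        Survival times and 1/0 death indicators.
    ties
        ``"efron"`` (default) or ``"breslow"`` tie handling.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size > 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if ties not in {"efron", "breslow"}:
        raise ValueError("ties must be 'efron' or 'breslow'")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        bad = [names[i] for i in np.nonzero(constant)[0]]
        raise ValueError(f"covariates constant across records: {bad}")
    warn_list: list[str] = []
    n_events = int(events.sum())
    if n_events < p:
        msg = f"fewer events ({n_events}) than covariates ({p})"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik_derivs(beta, X, times, events, ties)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        if np.max(np.abs(step)) < 1e-7:
            # gradient is at the floating-point noise floor of the
            # risk-set sums; the Newton increment no longer moves beta
            # (a 1e-7 increment changes the log likelihood by ~1e-13)
            converged = True
            break
        # step-halving keeps the likelihood monotone
        scale = 1.0
        for _half in range(30):
            candidate = beta + scale * step
            ll_new, grad_new, info_new = _cox_loglik_derivs(
                candidate, X, times, events, ties
            )
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        stalled = abs(ll_new - ll) < 1e-13 * (1.0 + abs(ll))
        beta, ll, grad, info = candidate, ll_new, grad_new, info_new
        if stalled:
            converged = True
            break
    else:
        if np.max(np.abs(grad)) >= tol:
            raise CoxConvergenceError(
                f"Newton failed to converge in {max_iter} iterations; "
                f"last max|gradient| = {np.max(np.abs(grad)):.3e}"
            )
        converged = True
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True

    if np.max(np.abs(beta)) > 20:
        msg = (
            "extreme coefficient magnitude suggests complete separation; "
            "estimates flagged"
        )
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "z": z,
            "p": pvals,
        },
        index=pd.Index(names, name="variable"),
    )
    return CoxResult(
        table=table,
        model=model,
        ties=ties,
        log_likelihood=float(ll),
        n=n,
        n_events=n_events,
        warnings=warn_list,
    )


# ---------------------------------------------------------------------------
# cohort-level helpers: design matrices and the variable-selection rules
# ---------------------------------------------------------------------------

DEMOGRAPHICS = ("age_at_surgery", "sex", "bmi", "family_history")


def build_survival_frame(
    cohort: Cohort, assignment: ClusterAssignment | None = None
) -> pd.DataFrame:
    """Analysis frame: time, event, demographics, surgery, cluster, term flags.

    Categorical encodings: ``sex`` -> female indicator; ``surgery`` ->
    3-level ordinal (repair=1, shunts=2, repair_plus_shunts=3), plus the
    cluster both as an ordinal column and as dummies with the smallest
    cluster (highest label) as the reference level.  Term columns are
    ``term_<id>`` presence flags from explicit annotations.
    """
    rows = []
    surgery_code = {"repair": 1, "shunts": 2, "repair_plus_shunts": 3}
    vocab = sorted({t for p in cohort for t in p.terms})
    for p in cohort:
        if p.time is None or p.event is None:
            raise ValueError(
                f"patient {p.patient_id!r} lacks survival time/event"
            )
        row = {
            "patient_id": p.patient_id,
            "time": p.time,
            "event": p.event,
            "age_at_surgery": p.age_at_surgery,
            "sex": 1.0 if p.sex == "female" else 0.0,
            "bmi": p.bmi,
            "family_history": (
                float(p.family_history) if p.family_history is not None else 0.0
            ),
            "surgery": float(surgery_code.get(p.surgery or "", np.nan)),
        }
        for t in vocab:
            row[f"term_{t}"] = 1.0 if t in p.terms else 0.0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    if assignment is not None:
        labels = assignment.labels_for(list(df.index))
        df["cluster"] = labels.astype(float)
        for c in range(1, assignment.k):  # largest k-1 clusters; smallest = ref
            df[f"cluster_{c}"] = (labels == c).astype(float)
    return df


def term_prevalence(cohort: Cohort) -> dict[str, float]:
    n = len(cohort)
    vocab = sorted({t for p in cohort for t in p.terms})
    return {
        t: sum(t in p.terms for p in cohort) / n for t in vocab
    }


def select_variables(
    cohort: Cohort,
    assignment: ClusterAssignment,
    stage: str,
    univariate_results: pd.DataFrame | None = None,
    low_prevalence: float = 0.05,
    high_prevalence: float = 0.25,
    alpha: float = 0.05,
) -> list[str]:
    """Variable roster for the univariate screen or the multivariate model.

    Univariate stage: cluster (ordinal), demographics, surgery type, and
    every term with prevalence above ``low_prevalence``.  Multivariate
    stage: the union of univariate-significant variables (p < ``alpha``),
    cluster dummies, demographics, surgery type, and terms above
    ``high_prevalence`` prevalence.
    """
    prev = term_prevalence(cohort)
    base = ["cluster", *DEMOGRAPHICS, "surgery"]
    if stage == "univariate":
        selected = base + [
            f"term_{t}" for t in sorted(prev) if prev[t] > low_prevalence
        ]
    elif stage == "multivariate":
        if univariate_results is None:
            raise ValueError("multivariate stage needs univariate results")
        significant = [
            v
            for v in univariate_results.index
            if univariate_results.loc[v, "p"] < alpha
        ]
        cluster_dummies = [f"cluster_{c}" for c in range(1, assignment.k)]
        selected = []
        for v in (
            cluster_dummies
            + list(DEMOGRAPHICS)
            + ["surgery"]
            + [f"term_{t}" for t in sorted(prev) if prev[t] > high_prevalence]
            + [v for v in significant if v != "cluster"]
        ):
            if v not in selected:
                selected.append(v)
    else:
        raise ValueError("stage must be 'univariate' or 'multivariate'")
    if not selected:
        raise ValueError("variable selection produced an empty roster")
    return selected


def _usable(df: pd.DataFrame, var: str) -> bool:
    col = df[var]
    return col.notna().all() and col.nunique() > 1


def univariate_cox_screen(
    df: pd.DataFrame, variables: list[str], ties: str = "efron"
) -> pd.DataFrame:
    """One single-covariate Cox fit per variable; rows ordered as given.

    Variables that are constant or have missing values are skipped with a
    log entry rather than failing the whole screen.
    """
    rows = []
    for var in variables:
        if var not in df.columns or not _usable(df, var):
            logger.warning("univariate screen: skipping unusable variable %s", var)
            continue
        res = cox_fit(
            df[[var]].to_numpy(),
            df["time"].to_numpy(),
            df["event"].to_numpy(),
            names=[var],
            ties=ties,
            model="univariate",
        )
        rows.append(res.table.loc[var])
    return pd.DataFrame(rows)


def multivariate_cox(
    df: pd.DataFrame, variables: list[str], ties: str = "efron"
) -> CoxResult:
    usable = [v for v in variables if v in df.columns and _usable(df, v)]
    dropped = sorted(set(variables) - set(usable))
    if dropped:
        logger.warning("multivariate model: dropping unusable variables %s", dropped)
    return cox_fit(
        df[usable].to_numpy(),
        df["time"].to_numpy(),
        df["event"].to_numpy(),
        names=usable,
        ties=ties,
        model="multivariate",
    )
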