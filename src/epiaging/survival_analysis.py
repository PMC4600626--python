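"""Inferential stage: rank tests, robust correlation, Cox models.

Covers the full analysis battery applied to IEAA and incident disease:
Kruskal-Wallis tests of IEAA by outcome/smoking groups, biweight
midcorrelation with pack-years, Cox proportional-hazards models (full
cohort and stratified by 10-year age group or smoking status), the
Breslow baseline cumulative hazard with covariate-profile incidence
curves, person-time accounting, and the landmark-exclusion and
logistic-regression sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "CoxFit",
    "StratumResult",
    "person_years_from_days",
    "kruskal_wallis",
    "bicor",
    "make_design",
    "cox_fit",
    "stratified_analysis",
    "predict_incidence",
    "landmark_exclusion",
    "logistic_sensitivity",
    "breslow_partial_loglik",
    "breslow_baseline_cumhaz",
]

FULL_COVARIATES = ["ieaa", "age", "black", "hispanic", "chd", "former", "current", "pack_years"]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    group_sizes: list[int] | None = None
    method: str = ""


@dataclass
class CoxFit:
    """Cox model estimates plus the Breslow baseline cumulative hazard.

    ``r_squared`` is the Cox-Snell-family index 1 - exp(2(ll0 - ll1)/n)
    computed from the null and fitted partial log-likelihoods.
    """

    summary: pd.DataFrame            # index covariates; log_hr, se, hr, p
    baseline_cumhaz: pd.Series       # H0 at distinct event times (covariates at 0)
    n: int
    n_events: int
    total_person_years: float
    log_likelihood: float
    null_log_likelihood: float
    r_squared: float
    max_observed_time: float
    ties: str = "breslow"
    warnings_: list[str] = field(default_factory=list)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.summary.index)


@dataclass
class StratumResult:
    name: str
    n: int
    n_events: int
    person_years: float
    fit: CoxFit | None
    error: str | None = None
    dropped_covariates: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Person-time

def person_years_from_days(days):
    """Convert follow-up days to person-years (days/365.25) at 4-decimal
    precision."""
    days = np.asarray(days, dtype=float)
    if np.any(~np.isfinite(days)) or np.any(days < 0):
        raise ValueError("days must be finite and nonnegative")
    out = np.round(days / 365.25, 4)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Rank test & robust correlation

def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with a chi-square p on k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in pd.unique(groups)]
    arrays = [a for a in arrays if a.size]
    if len(arrays) < 2:
        raise ValueError("need at least two non-empty groups")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(values) == 0:
        raise ValueError("degenerate data: all values identical (tie "
                         "correction denominator is zero)")
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), [a.size for a in arrays], "kruskal-wallis")


def bicor(x, y, fallback_to_pearson: bool = True) -> TestResult:
    """Biweight midcorrelation, a median/MAD-based robust correlation.

    Observations are weighted by (1-u^2)^2 for |u| < 1 with
    u = (x - median) / (9 MAD); the p-value uses the Student-t
    approximation with n-2 df.  When either vector has zero MAD the
    estimator is undefined; with ``fallback_to_pearson`` the Pearson
    correlation is returned (with a warning) instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need two equal-length vectors with n >= 5")
    n = x.size

    def _weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    xt, yt = _weighted(x), _weighted(y)
    if xt is None or yt is None:
        if not fallback_to_pearson:
            raise ValueError("zero median absolute deviation: biweight "
                             "midcorrelation undefined")
        warnings.warn("zero MAD; falling back to Pearson correlation")
        r, p = stats.pearsonr(x, y)
        return TestResult(float(r), float(p), [n], "pearson-fallback")

    r = float(np.dot(xt, yt) / np.sqrt(np.dot(xt, xt) * np.dot(yt, yt)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return TestResult(r, p, [n], "bicor")


# ---------------------------------------------------------------------------
# Cox proportional hazards

def make_design(phenotypes: pd.DataFrame, ieaa: pd.Series | None = None) -> pd.DataFrame:
    """Expand the phenotype table into the model design.

    Reference categories: never smoker and non-Hispanic white (only
    former/current and Black/Hispanic indicators enter the model).
    """
    df = pd.DataFrame(index=phenotypes.index)
    if ieaa is not None:
        df["ieaa"] = ieaa
    df["age"] = phenotypes["age"]
    race = phenotypes["race_ethnicity"].astype(str).str.lower()
    df["black"] = (race == "black").astype(float)
    df["hispanic"] = (race == "hispanic").astype(float)
    df["chd"] = phenotypes["chd"].astype(float)
    smoke = phenotypes["smoking_status"].astype(str).str.lower()
    df["former"] = (smoke == "former").astype(float)
    df["current"] = (smoke == "current").astype(float)
    df["pack_years"] = phenotypes["pack_years"].astype(float)
    df["time"] = phenotypes["time"].astype(float)
    df["event"] = phenotypes["event"].astype(int)
    if ieaa is not None:
        df = df.dropna(subset=["ieaa"])
    return df


def breslow_partial_loglik(X, beta, time, event) -> float:
    """Cox partial log-likelihood with Breslow tie handling."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = X @ beta
    order = np.argsort(-time)  # decreasing time: risk set grows as we walk
    eta_s, t_s, e_s = eta[order], time[order], event[order]
    ll = 0.0
    cum = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        cum += np.exp(eta_s[i:j]).sum()  # all subjects at this time enter risk set
        ev = e_s[i:j] == 1
        d = int(ev.sum())
        if d:
            ll += eta_s[i:j][ev].sum() - d * np.log(cum)
        i = j
    return float(ll)


def breslow_baseline_cumhaz(X, beta, time, event) -> pd.Series:
    """Breslow estimator of the baseline cumulative hazard H0 (covariates
    at zero), stepping at each distinct event time."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.exp(X @ np.asarray(beta, dtype=float))
    event_times = np.unique(time[event == 1])
    jumps = np.empty(event_times.size)
    for k, t in enumerate(event_times):
        d = int(((time == t) & (event == 1)).sum())
        jumps[k] = d / risk[time >= t].sum()
    return pd.Series(np.cumsum(jumps), index=event_times, name="baseline_cumhaz")


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxFit:
    """Fit a Cox proportional-hazards model (lifelines backend).

    Raises on zero events, constant covariates, rank-deficient designs,
    and non-convergence from a monotone partial likelihood (perfect
    separation), naming the offending covariate where possible.
    """
    data = df[covariates + [duration_col, event_col]].dropna()
    n = len(data)
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise ValueError("no events: Cox partial likelihood is undefined")
    X = data[covariates].to_numpy(dtype=float)
    const = [c for c in covariates if data[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(covariates):
        raise ValueError("rank-deficient design matrix")

    cph = CoxPHFitter(baseline_estimation_method="breslow")
    caught: list[str] = []
    # Near-collinear covariates (e.g. smoking dummies vs pack-years) can make
    # the full Newton step oscillate; retry with damped steps before giving up.
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", ConvergenceWarning)
        last_err: Exception | None = None
        for step in (None, 0.5, 0.25):
            try:
                opts = {} if step is None else {"fit_options": {"step_size": step}}
                cph.fit(data, duration_col=duration_col, event_col=event_col, **opts)
                last_err = None
                break
            except ConvergenceError as err:
                last_err = err
        if last_err is not None:
            raise ValueError(
                "Cox model did not converge (likely monotone likelihood / "
                f"perfect separation): {last_err}"
            ) from last_err
        caught = [str(w.message) for w in wlist if issubclass(w.category, ConvergenceWarning)]

    beta = cph.params_.reindex(covariates).to_numpy()
    se = cph.standard_errors_.reindex(covariates).to_numpy()
    p = cph.summary["p"].reindex(covariates).to_numpy()
    summary = pd.DataFrame(
        {"log_hr": beta, "se": se, "hr": np.exp(beta), "p": p}, index=covariates
    )

    time = data[duration_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=int)
    ll1 = float(cph.log_likelihood_)
    ll0 = breslow_partial_loglik(X, np.zeros(len(covariates)), time, event)
    r2 = float(1.0 - np.exp(2.0 * (ll0 - ll1) / n))
    h0 = breslow_baseline_cumhaz(X, beta, time, event)

    return CoxFit(
        summary=summary,
        baseline_cumhaz=h0,
        n=n,
        n_events=n_events,
        total_person_years=float(time.sum()),
        log_likelihood=ll1,
        null_log_likelihood=ll0,
        r_squared=r2,
        max_observed_time=float(time.max()),
        ties=ties,
        warnings_=caught,
    )


# ---------------------------------------------------------------------------
# Stratified models

AGE_STRATA = (("50-59", 0.0, 60.0), ("60-69", 60.0, 70.0), ("70+", 70.0, np.inf))


def stratified_analysis(
    phenotypes: pd.DataFrame,
    ieaa: pd.Series,
    strata_spec: str,
) -> list[StratumResult]:
    """Per-stratum Cox fits.

    ``strata_spec='age'`` splits into 10-year baseline age groups
    ([50,60), [60,70), 70+ — left-closed) keeping the full covariate set;
    ``'smoking'`` splits by smoking status with the smoking dummies
    removed and pack-years additionally omitted for never smokers (it is
    identically zero there).  Standardized IEAA is taken as passed in —
    computed once on the full cohort, not re-standardized per stratum.
    Strata where the model is unestimable are reported as such, never
    silently dropped; covariates constant within a stratum are dropped
    with a record.
    """
    design = make_design(phenotypes, ieaa)
    results: list[StratumResult] = []

    if strata_spec == "age":
        pieces = [
            (name, design[(design["age"] >= lo) & (design["age"] < hi)], FULL_COVARIATES)
            for name, lo, hi in AGE_STRATA
        ]
    elif strata_spec == "smoking":
        covs = ["ieaa", "age", "black", "hispanic", "chd", "pack_years"]
        smoke = phenotypes["smoking_status"].astype(str).str.lower().reindex(design.index)
        pieces = []
        for status in ("current", "former", "never"):
            sub = design[smoke == status]
            c = [c for c in covs if not (status == "never" and c == "pack_years")]
            pieces.append((status, sub, c))
    else:
        raise ValueError(f"unknown strata_spec: {strata_spec!r}")

    for name, sub, covs in pieces:
        n = len(sub)
        n_events = int(sub["event"].sum()) if n else 0
        py = float(sub["time"].sum()) if n else 0.0
        if n == 0 or n_events == 0:
            results.append(StratumResult(name, n, n_events, py, None,
                                         error="no subjects" if n == 0 else "no events"))
            continue
        usable = [c for c in covs if sub[c].nunique() > 1]
        dropped = [c for c in covs if c not in usable]
        try:
            fit = cox_fit(sub, usable)
            results.append(StratumResult(name, n, n_events, py, fit,
                                         dropped_covariates=dropped))
        except ValueError as err:
            results.append(StratumResult(name, n, n_events, py, None,
                                         error=str(err), dropped_covariates=dropped))
    return results


# ---------------------------------------------------------------------------
# Covariate-profile incidence curves

def predict_incidence(fit: CoxFit, profile: dict, times) -> pd.Series:
    """Predicted cumulative incidence 1 - exp(-H0(t) exp(x'beta)) for a
    covariate profile, e.g. {age: 75, white, current smoker, 30
    pack-years} at standardized IEAA in {-1, 0, 1}.

    ``profile`` must supply a value for every fitted covariate.  Beyond
    the last observed follow-up time the curve is extended flat (with a
    warning).
    """
    missing = [c for c in fit.covariate_names if c not in profile]
    if missing:
        raise ValueError(f"profile missing covariates: {missing}")
    times = np.asarray(times, dtype=float)
    if np.any(times > fit.max_observed_time):
        warnings.warn("requested times beyond last observed follow-up; "
                      "curve extended flat")
    x = np.array([profile[c] for c in fit.covariate_names], dtype=float)
    xb = float(x @ fit.summary["log_hr"].to_numpy())
    jump_times = fit.baseline_cumhaz.index.to_numpy()
    h0 = np.concatenate([[0.0], fit.baseline_cumhaz.to_numpy()])
    idx = np.searchsorted(jump_times, times, side="right")
    inc = 1.0 - np.exp(-h0[idx] * np.exp(xb))
    return pd.Series(inc, index=times, name="incidence")


# ---------------------------------------------------------------------------
# Sensitivity analyses

def landmark_exclusion(phenotypes: pd.DataFrame, exclude_within: float):
    """Drop subjects whose event occurred within ``exclude_within`` years
    of baseline (censored subjects are retained regardless of time);
    returns (filtered table, number excluded)."""
    if exclude_within < 0:
        raise ValueError("exclude_within must be nonnegative")
    drop = (phenotypes["event"] == 1) & (phenotypes["time"] < exclude_within)
    return phenotypes[~drop].copy(), int(drop.sum())


def logistic_sensitivity(
    phenotypes: pd.DataFrame,
    ieaa: pd.Series,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Logistic regression of the event indicator on the Cox covariate set
    (follow-up time ignored); for a rare outcome the odds ratios
    approximate the hazard ratios."""
    design = make_design(phenotypes, ieaa)
    covariates = covariates or FULL_COVARIATES
    data = design[covariates + ["event"]].dropna()
    y = data["event"].to_numpy()
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(data[covariates])
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as err:  # statsmodels PerfectSeparationError et al.
        raise ValueError(f"logistic fit failed (possible perfect separation): {err}") from err
    params = res.params.drop("const")
    out = pd.DataFrame(
        {
            "log_or": params,
            "se": res.bse.drop("const"),
            "odds_ratio": np.exp(params),
            "p": res.pvalues.drop("const"),
        }
    )
    return out
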