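"""Kaplan-Meier estimation, log-rank tests, Cox proportional hazards, a
per-gene prognostic screen, and contingency tests for subtype tables.

The product-limit and log-rank O/E/V aggregations are computed directly (the
cutpoint search in :mod:`icpattern.signature` consumes the raw standardized
statistic); Cox models are fit by partial likelihood via statsmodels' PHReg
with Efron or Breslow tie handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency, fisher_exact
from statsmodels.duration.hazard_regression import PHReg

from .io import ExpressionMatrix

__all__ = [
    "KMCurve",
    "TestResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "contingency_test",
]


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times t_j
    at_risk: np.ndarray  # n_j
    events: np.ndarray  # d_j
    survival: np.ndarray  # S(t_j)
    greenwood_var: np.ndarray  # Var[S(t_j)] by Greenwood's formula

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray | None = None
    expected: np.ndarray | None = None
    variance: np.ndarray | None = None
    table: pd.DataFrame | None = None
    odds_ratio: float | None = None
    method: str = ""


@dataclass
class CoxResult:
    beta: pd.Series
    hazard_ratio: pd.Series
    se: pd.Series
    ci_lower: pd.Series  # on the hazard-ratio scale
    ci_upper: pd.Series
    p_value: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    ties: str
    warnings: list[str] = field(default_factory=list)


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival data")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censorings at an event time count as at-risk for that time's events
    (censored-after-event tie convention).
    """
    times, events = _check_surv(times, events)
    t_ev = np.unique(times[events == 1])
    if t_ev.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]), np.array([]), np.array([]))
    n_j = np.array([(times >= t).sum() for t in t_ev], dtype=float)
    d_j = np.array([((times == t) & (events == 1)).sum() for t in t_ev], dtype=float)
    s = np.cumprod(1.0 - d_j / n_j)
    # Greenwood: Var[S] = S^2 * sum d/(n(n-d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d_j / (n_j * (n_j - d_j))
    terms[~np.isfinite(terms)] = 0.0
    var = s ** 2 * np.cumsum(terms)
    return KMCurve(t_ev, n_j, d_j, s, var)


def logrank_test(times, events, groups) -> TestResult:
    """k-group log-rank test via the standard O/E/V aggregation.

    Returns the chi-square statistic with df = k - 1, per-group observed and
    expected event counts, and the full covariance matrix of O - E.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if events.sum() == 0:
        raise ValueError("no events observed")

    t_ev = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in t_ev:
        at_risk = times >= t
        N = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_g = np.bincount(codes[at_risk], minlength=k).astype(float)
        O += np.bincount(codes[(times == t) & (events == 1)], minlength=k)
        E += d * n_g / N
        if N > 1:
            p = n_g / N
            V += d * (N - d) / (N - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(chi2.sf(stat, k - 1))
    return TestResult(statistic=stat, df=k - 1, p_value=p,
                      observed=O, expected=E, variance=V, method="logrank")


def logrank_z(times, events, mask) -> float:
    """Standardized two-group log-rank statistic (O - E)/sqrt(V) for mask vs rest."""
    res = logrank_test(times, events, np.asarray(mask).astype(int))
    v = res.variance[0, 0]
    if v <= 0:
        return 0.0
    return float((res.observed[0] - res.expected[0]) / np.sqrt(v))


def cox_fit(
    data: pd.DataFrame,
    covariate_names: list[str],
    time_col: str = "os_time",
    event_col: str = "os_event",
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit by partial likelihood.

    ``data`` holds time, event and covariate columns (continuous or already
    one-hot encoded).  Wald 95% intervals are reported on the hazard-ratio
    scale.  Monotone-likelihood separation (|beta| > 20) is flagged as
    non-convergence.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    times, events = _check_surv(data[time_col], data[event_col])
    if events.sum() == 0:
        raise ValueError("no events observed")
    X = data[covariate_names].to_numpy(dtype=float)
    sds = X.std(axis=0)
    const = [c for c, s in zip(covariate_names, sds) if s == 0]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank deficient")

    model = PHReg(times, X, status=events, ties=ties)
    res = model.fit(disp=False)
    beta = pd.Series(res.params, index=covariate_names, name="beta")
    se = pd.Series(res.bse, index=covariate_names, name="se")
    warns = []
    converged = bool(np.isfinite(beta).all())
    if not converged:
        warns.append("Cox fit did not converge: non-finite coefficients")
        warnings.warn(warns[-1])
    elif (beta.abs() > 20).any():
        converged = False
        warns.append("possible monotone-likelihood separation: |beta| > 20")
        warnings.warn(warns[-1])
    lo = np.exp(beta - 1.96 * se)
    hi = np.exp(beta + 1.96 * se)
    return CoxResult(
        beta=beta,
        hazard_ratio=np.exp(beta).rename("HR"),
        se=se,
        ci_lower=lo.rename("ci_lower"),
        ci_upper=hi.rename("ci_upper"),
        p_value=pd.Series(res.pvalues, index=covariate_names, name="p"),
        log_likelihood=float(model.loglike(res.params)),
        n=len(times),
        n_events=int(events.sum()),
        converged=converged,
        ties=ties,
        warnings=warns,
    )


def univariate_screen(expr: ExpressionMatrix, survival: pd.DataFrame) -> pd.DataFrame:
    """Per-gene prognostic screen over aligned samples.

    For each gene: univariate Cox beta/HR/p on continuous expression, the
    log-rank p for a median split, and a favorable/poor direction label from
    the sign of beta.  Per-gene failures (e.g. constant genes) are recorded as
    missing rows, not fatal.
    """
    common = [s for s in expr.samples if s in survival.index]
    surv = survival.loc[common]
    times, events = _check_surv(surv["os_time"], surv["os_event"])
    rows = []
    for gene in expr.genes:
        x = expr.values.loc[gene, common].to_numpy(dtype=float)
        row = {"gene": gene, "beta": np.nan, "HR": np.nan, "cox_p": np.nan,
               "logrank_p": np.nan, "direction": ""}
        if np.ptp(x) == 0:
            warnings.warn(f"gene {gene}: constant expression, screen skipped")
            rows.append(row)
            continue
        try:
            df = pd.DataFrame({"os_time": times, "os_event": events, "x": x})
            cf = cox_fit(df, ["x"])
            row.update(beta=float(cf.beta["x"]), HR=float(cf.hazard_ratio["x"]),
                       cox_p=float(cf.p_value["x"]),
                       direction="poor" if cf.beta["x"] > 0 else "favorable")
            split = (x > np.median(x)).astype(int)
            if 0 < split.sum() < len(split):
                row["logrank_p"] = logrank_test(times, events, split).p_value
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"gene {gene}: screen failed ({exc})")
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def _odds_ratio(table: np.ndarray) -> float:
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane-Anscombe
    return float(a * d / (b * c))


def contingency_test(a, b) -> TestResult:
    """Association between two categorical vectors.

    2x2 tables use the Fisher exact test (two-sided by the point-probability
    method) with a Haldane-corrected odds ratio when a cell is zero; larger
    tables use the Pearson chi-square with df = (r-1)(c-1).
    """
    a = pd.Series(a).astype(str)
    b = pd.Series(b).astype(str)
    if len(a) != len(b):
        raise ValueError("inputs must have equal length")
    table = pd.crosstab(a, b)
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("each factor needs at least 2 nonempty levels")
    arr = table.to_numpy()
    if table.shape == (2, 2):
        _, p = fisher_exact(arr, alternative="two-sided")
        return TestResult(statistic=np.nan, df=1, p_value=float(p), table=table,
                          odds_ratio=_odds_ratio(arr), method="fisher")
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), df=int(dof), p_value=float(p),
                      table=table, method="chi2")
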