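"""Survival engine: Kaplan-Meier, log-rank, univariate Cox, cutoff scan.

Implements the expression-dichotomization methodology used for cohort
survival analysis: every candidate expression cutoff between the lower
and upper quartiles is scored by univariate Cox proportional-hazards
regression on the resulting high/low indicator, the best-performing
cutoff (smallest likelihood-ratio p) defines the final groups, and the
final report carries Kaplan-Meier curves, the log-rank p-value and the
hazard ratio with its 95% confidence interval.

The scanned minimum p-value is selection-optimistic by construction;
every scan result carries a ``cutoff_optimized`` caveat flag and the
package applies no correction by default.

The Cox partial likelihood uses the Efron approximation for tied event
times and is maximized by Newton iterations on the scalar coefficient
(gradient tolerance 1e-8, at most 100 iterations). With a binary
covariate and no ties, the Cox score test is algebraically identical to
the two-group log-rank test; both routes are implemented independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 100
Z_95 = 1.96  # normal quantile for the 95% CI on the log-hazard scale


class DegenerateCovariateError(ValueError):
    """Covariate is constant (or a group is empty): no contrast to fit."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the gradient tolerance."""


# ---------------------------------------------------------------------------
# cohort validation


def validate_cohort(cohort: pd.DataFrame, require_expression: bool = False) -> pd.DataFrame:
    """Check the (time, event[, expression]) contract of a cohort table."""
    for column in ("time", "event"):
        if column not in cohort.columns:
            raise ValidationError(f"cohort missing column {column!r}")
    if (cohort["time"] <= 0).any():
        raise ValidationError("follow-up times must be > 0")
    if not cohort["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 (censored) or 1 (event)")
    if require_expression:
        if "expression" not in cohort.columns:
            raise ValidationError("cohort missing column 'expression'")
        if cohort["expression"].isna().any():
            raise ValidationError("missing expression values not allowed for the cutoff scan")
    return cohort


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival estimate on the grid of distinct observed times.

    ``table`` columns: time, n_risk, n_event, n_censored, survival,
    greenwood_var. Censoring at t removes subjects from the risk set
    after t, so the estimate only steps down at event times.
    """

    table: pd.DataFrame
    n_subjects: int

    def survival_at(self, t: float) -> float:
        steps = self.table[self.table["time"] <= t]
        return 1.0 if steps.empty else float(steps["survival"].iloc[-1])


def km_estimate(time: np.ndarray | pd.Series, event: np.ndarray | pd.Series) -> KMCurve:
    """Kaplan-Meier estimate for one group of subjects."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValidationError("km_estimate requires at least one subject")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    times, first = np.unique(t, return_index=True)
    counts = np.diff(np.append(first, t.size))
    d = np.add.reduceat(e, first)  # events per distinct time
    n_risk = t.size - first  # at risk just before each distinct time
    frac = np.where(n_risk > 0, 1.0 - d / n_risk, 1.0)
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
        gw_terms = np.where(d > 0, gw_terms, 0.0)
        greenwood = survival**2 * np.cumsum(gw_terms)
    # the variance is 0 (not inf) once the estimate itself has reached 0
    greenwood = np.where(np.isfinite(greenwood), greenwood, 0.0)
    table = pd.DataFrame(
        {
            "time": times,
            "n_risk": n_risk,
            "n_event": d,
            "n_censored": counts - d,
            "survival": survival,
            "greenwood_var": greenwood,
        }
    )
    return KMCurve(table, n_subjects=int(t.size))


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float
    observed: tuple[float, float]  # events per group
    expected: tuple[float, float]
    degenerate: bool = False


def logrank(
    time_a: np.ndarray | pd.Series,
    event_a: np.ndarray | pd.Series,
    time_b: np.ndarray | pd.Series,
    event_b: np.ndarray | pd.Series,
) -> LogrankResult:
    """Two-group log-rank test with hypergeometric variance at each event time."""
    ta, ea = np.asarray(time_a, dtype=float), np.asarray(event_a, dtype=int)
    tb, eb = np.asarray(time_b, dtype=float), np.asarray(event_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups need at least one subject")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    total_events = int(e.sum())
    if total_events == 0:
        return LogrankResult(0.0, 1.0, (0.0, 0.0), (0.0, 0.0), degenerate=True)

    event_times = np.unique(t[e == 1])
    # at-risk and event counts at each distinct event time, per group
    n_a = (ta[None, :] >= event_times[:, None]).sum(axis=1)
    n_b = (tb[None, :] >= event_times[:, None]).sum(axis=1)
    d_a = ((ta[None, :] == event_times[:, None]) & (ea[None, :] == 1)).sum(axis=1)
    d_b = ((tb[None, :] == event_times[:, None]) & (eb[None, :] == 1)).sum(axis=1)
    n_tot = n_a + n_b
    d_tot = d_a + d_b

    expected_a = d_tot * n_a / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = (
            d_tot * (n_a / n_tot) * (n_b / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        )
    var_terms = np.where(n_tot > 1, var_terms, 0.0)
    observed = float(d_a.sum())
    expected = float(expected_a.sum())
    variance = float(var_terms.sum())
    if variance <= 0:
        return LogrankResult(
            0.0, 1.0, (observed, float(d_b.sum())),
            (expected, total_events - expected), degenerate=True,
        )
    chi2 = (observed - expected) ** 2 / variance
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(
        float(chi2), p,
        (observed, float(d_b.sum())),
        (expected, total_events - expected),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, Efron ties)


@dataclass
class CoxFit:
    coef: float  # log-hazard per covariate unit
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_lrt: float
    p_score: float
    log_likelihood: float
    null_log_likelihood: float
    n_subjects: int
    n_events: int
    n_iter: int
    ties: str = "efron"


def _efron_quantities(
    beta: float,
    t: np.ndarray,
    e: np.ndarray,
    x: np.ndarray,
) -> tuple[float, float, float]:
    """Partial log-likelihood, gradient and information at beta.

    Inputs must be sorted by ascending time. Uses the Efron correction:
    within a tied death set the deaths leave the risk set gradually, each
    of the d tied subjects contributing a fraction l/d of the death-set
    weight at step l.
    """
    w = np.exp(beta * x)
    # reverse-cumulative risk-set sums, indexed at the first row of each time
    rc0 = np.cumsum(w[::-1])[::-1]
    rc1 = np.cumsum((w * x)[::-1])[::-1]
    rc2 = np.cumsum((w * x * x)[::-1])[::-1]

    ev = e == 1
    if not ev.any():
        return 0.0, 0.0, 0.0
    et = t[ev]
    ex = x[ev]
    ew = w[ev]
    times, inverse, counts = np.unique(et, return_inverse=True, return_counts=True)
    idx = np.searchsorted(t, times, side="left")
    S0, S1, S2 = rc0[idx], rc1[idx], rc2[idx]
    D0 = np.bincount(inverse, weights=ew)
    D1 = np.bincount(inverse, weights=ew * ex)
    D2 = np.bincount(inverse, weights=ew * ex * ex)

    # one row per (event-time, l) pair, l = 0..d_j - 1
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    l = np.arange(et.size) - np.repeat(starts, counts)
    frac = l / np.repeat(counts, counts)
    rep = np.repeat(np.arange(times.size), counts)
    phi = S0[rep] - frac * D0[rep]
    psi1 = S1[rep] - frac * D1[rep]
    psi2 = S2[rep] - frac * D2[rep]

    loglik = float(beta * ex.sum() - np.log(phi).sum())
    gradient = float(ex.sum() - (psi1 / phi).sum())
    information = float((psi2 / phi - (psi1 / phi) ** 2).sum())
    return loglik, gradient, information


def cox_fit(
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    covariate: np.ndarray | pd.Series,
) -> CoxFit:
    """Univariate Cox PH fit by Newton iterations on the partial likelihood."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateCovariateError("covariate is constant; no hazard contrast to estimate")
    if int(e.sum()) < 2:
        raise ValidationError("Cox fit requires at least 2 events")

    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    # center for numerical stability; the partial likelihood is invariant
    shift = x.mean()
    xc = x - shift

    null_ll, score_u, score_i = _efron_quantities(0.0, t, e, xc)
    beta = 0.0
    loglik, gradient, information = null_ll, score_u, score_i
    n_iter = 0
    for n_iter in range(1, NEWTON_MAX_ITER + 1):
        if abs(gradient) < NEWTON_TOL:
            break
        if information <= 0:
            raise ConvergenceError(
                f"non-positive information {information} at beta={beta} (iteration {n_iter})"
            )
        step = gradient / information
        # step-halving keeps the likelihood non-decreasing
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_quantities(new_beta, t, e, xc)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_quantities(new_beta, t, e, xc)
            halvings += 1
        beta, loglik, gradient, information = new_beta, new_ll, new_grad, new_info
    else:
        raise ConvergenceError(
            f"no convergence in {NEWTON_MAX_ITER} iterations: "
            f"beta={beta}, gradient={gradient}, loglik={loglik}"
        )

    se = float(np.sqrt(1.0 / information))
    wald = (beta / se) ** 2
    lrt = 2.0 * (loglik - null_ll)
    score = score_u**2 / score_i if score_i > 0 else 0.0
    return CoxFit(
        coef=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p_wald=float(stats.chi2.sf(wald, df=1)),
        p_lrt=float(stats.chi2.sf(max(lrt, 0.0), df=1)),
        p_score=float(stats.chi2.sf(score, df=1)),
        log_likelihood=float(loglik),
        null_log_likelihood=float(null_ll),
        n_subjects=int(t.size),
        n_events=int(e.sum()),
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# quartile-restricted cutoff scan


@dataclass
class CutoffScanResult:
    """Outcome of scoring every candidate expression cutoff in [Q1, Q3].

    ``candidates`` has one row per scanned cutoff (group sizes, Cox
    summary, likelihood-ratio and Wald p, an ``ok`` flag for fittable
    splits). ``cutoff_optimized`` is always True: the selected p-value is
    a minimum over the scan and is optimistic relative to a prespecified
    cutoff.
    """

    candidates: pd.DataFrame
    selected_cutoff: float
    n_low: int
    n_high: int
    cox: CoxFit
    logrank: LogrankResult
    km_low: KMCurve
    km_high: KMCurve
    cutoff_optimized: bool = True


def _dichotomize(expression: np.ndarray, cutoff: float) -> np.ndarray:
    # high-expression group is strictly above the cutoff
    return (expression > cutoff).astype(float)


def quartile_cutoff_scan(cohort: pd.DataFrame, min_subjects: int = 20) -> CutoffScanResult:
    """Scan every distinct expression value between Q1 and Q3 as a cutoff.

    Each candidate dichotomizes the cohort (high iff expression > cutoff)
    and is scored by univariate Cox regression on the indicator; the
    cutoff with the smallest likelihood-ratio p is selected (ties broken
    toward the median, then toward the lower value).
    """
    validate_cohort(cohort, require_expression=True)
    if len(cohort) < min_subjects:
        raise ValidationError(f"cutoff scan requires >= {min_subjects} subjects")
    expr = cohort["expression"].to_numpy(dtype=float)
    if np.ptp(expr) == 0.0:
        raise DegenerateCovariateError("expression is constant; no cutoff to scan")
    t = cohort["time"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)

    q1, q3 = np.quantile(expr, [0.25, 0.75])
    median = float(np.quantile(expr, 0.5))
    values = np.unique(expr)
    candidates = values[(values >= q1) & (values <= q3)]

    rows = []
    for cutoff in candidates:
        z = _dichotomize(expr, cutoff)
        n_high = int(z.sum())
        n_low = int(z.size - n_high)
        row: dict[str, object] = {
            "cutoff": float(cutoff), "n_low": n_low, "n_high": n_high,
            "coef": np.nan, "hazard_ratio": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "p_lrt": np.nan, "p_wald": np.nan, "ok": False,
        }
        if n_low and n_high:
            try:
                fit = cox_fit(t, e, z)
            except (DegenerateCovariateError, ValidationError, ConvergenceError):
                fit = None
            if fit is not None:
                row.update(
                    coef=fit.coef, hazard_ratio=fit.hazard_ratio,
                    ci_low=fit.ci_low, ci_high=fit.ci_high,
                    p_lrt=fit.p_lrt, p_wald=fit.p_wald, ok=True,
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    usable = table[table["ok"]]
    if usable.empty:
        raise ValidationError("cutoff scan failed: no candidate produced a fittable split")

    best_p = usable["p_lrt"].min()
    at_best = usable[usable["p_lrt"] == best_p].copy()
    at_best["median_distance"] = (at_best["cutoff"] - median).abs()
    at_best = at_best.sort_values(["median_distance", "cutoff"], kind="mergesort")
    selected = float(at_best["cutoff"].iloc[0])

    z = _dichotomize(expr, selected).astype(bool)
    fit = cox_fit(t, e, z.astype(float))
    lr = logrank(t[~z], e[~z], t[z], e[z])
    return CutoffScanResult(
        candidates=table,
        selected_cutoff=selected,
        n_low=int((~z).sum()),
        n_high=int(z.sum()),
        cox=fit,
        logrank=lr,
        km_low=km_estimate(t[~z], e[~z]),
        km_high=km_estimate(t[z], e[z]),
    )


# ---------------------------------------------------------------------------
# assembled report


@dataclass
class SurvivalReport:
    """Dichotomized-cohort survival summary in a table-ready layout."""

    mode: str
    cutoff: float
    n_low: int
    n_high: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float
    cox: CoxFit
    km_low: KMCurve
    km_high: KMCurve
    cutoff_optimized: bool
    scan: CutoffScanResult | None = None

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "cutoff": self.cutoff,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "hazard_ratio": self.hazard_ratio,
            "ci_95": [self.ci_low, self.ci_high],
            "logrank_p": self.logrank_p,
            "cox_lrt_p": self.cox.p_lrt,
            "cutoff_optimized": self.cutoff_optimized,
        }


def survival_report(
    cohort: pd.DataFrame, mode: str = "scan", cutoff: float | None = None
) -> SurvivalReport:
    """Dichotomize a cohort and report KM curves, log-rank p, HR with CI.

    Modes: ``scan`` (quartile-restricted cutoff scan), ``median`` (split
    at the median expression), ``fixed`` (caller-supplied cutoff; both
    groups must be non-empty).
    """
    validate_cohort(cohort, require_expression=True)
    expr = cohort["expression"].to_numpy(dtype=float)
    t = cohort["time"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=int)

    if mode == "scan":
        scan = quartile_cutoff_scan(cohort)
        return SurvivalReport(
            mode=mode, cutoff=scan.selected_cutoff,
            n_low=scan.n_low, n_high=scan.n_high,
            hazard_ratio=scan.cox.hazard_ratio,
            ci_low=scan.cox.ci_low, ci_high=scan.cox.ci_high,
            logrank_p=scan.logrank.p_value, cox=scan.cox,
            km_low=scan.km_low, km_high=scan.km_high,
            cutoff_optimized=True, scan=scan,
        )
    if mode == "median":
        cut = float(np.quantile(expr, 0.5))
    elif mode == "fixed":
        if cutoff is None:
            raise ValueError("mode='fixed' requires a cutoff")
        cut = float(cutoff)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    z = expr > cut
    if not z.any() or z.all():
        raise ValidationError(
            f"cutoff {cut} leaves an empty group (expression range "
            f"[{expr.min()}, {expr.max()}])"
        )
    fit = cox_fit(t, e, z.astype(float))
    lr = logrank(t[~z], e[~z], t[z], e[z])
    return SurvivalReport(
        mode=mode, cutoff=cut,
        n_low=int((~z).sum()), n_high=int(z.sum()),
        hazard_ratio=fit.hazard_ratio, ci_low=fit.ci_low, ci_high=fit.ci_high,
        logrank_p=lr.p_value, cox=fit,
        km_low=km_estimate(t[~z], e[~z]), km_high=km_estimate(t[z], e[z]),
        cutoff_optimized=False,
    )
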