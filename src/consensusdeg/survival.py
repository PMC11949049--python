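"""Median-split Kaplan-Meier, log-rank test, and univariate Cox regression.

Survival handling mirrors common clinical-cohort practice for per-gene
prognosis screens: each gene's expression median-splits the cohort into
"high" and "low" groups, group survival is summarized by the product-limit
(Kaplan-Meier) estimator and compared with the log-rank test; the same gene
is also fit as a continuous covariate in a univariate Cox proportional-
hazards model (Breslow tie handling) with Wald p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .strata import split_by_median

logger = logging.getLogger(__name__)

__all__ = [
    "kaplan_meier",
    "km_median_split",
    "logrank_test",
    "cox_univariate",
    "multi_cohort_summary",
    "CoxConvergenceError",
]


class CoxConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (trace attached)."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


def _validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table lacks required column {col!r}")
    if surv.index.duplicated().any():
        raise ValueError("survival table has duplicate sample IDs")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (observed)")
    return surv


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate; rows at each distinct event time.

    Columns: ``time``, ``n_risk``, ``n_event``, ``survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        n_risk = int((times >= t).sum())
        n_event = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - n_event / n_risk
        rows.append((t, n_risk, n_event, s))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival"])


def median_survival(km: pd.DataFrame) -> float:
    """First event time at which the survival curve reaches <= 0.5 (NaN if never)."""
    hit = km[km["survival"] <= 0.5]
    return float(hit["time"].iloc[0]) if len(hit) else float("nan")


def km_median_split(
    expr: pd.Series, surv: pd.DataFrame
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Median-split samples on a gene's expression; KM estimate per group.

    Samples at or below the median go to "low" (shared convention with
    strata.split_by_median).  Returns ``(labels, {"high": km, "low": km})``.
    """
    surv = _validate_survival(surv)
    expr = expr.reindex(surv.index)
    if expr.isna().any():
        raise ValueError("expression missing for some survival samples")
    labels = split_by_median(expr)
    curves = {}
    for grp in ("high", "low"):
        members = labels.index[labels == grp]
        if len(members) < 2:
            raise ValueError(f"median split leaves <2 samples in group {grp!r}")
        curves[grp] = kaplan_meier(
            surv.loc[members, "time"].to_numpy(), surv.loc[members, "event"].to_numpy()
        )
    return labels, curves


def logrank_test(labels: pd.Series, surv: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (O - E)^2 / V, 1 df.

    O, E and the hypergeometric variance V are summed over distinct event
    times of the pooled sample.
    """
    surv = _validate_survival(surv)
    groups = labels.reindex(surv.index)
    uniq = sorted(groups.dropna().unique())
    if len(uniq) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {uniq}")
    times = surv["time"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=int)
    in1 = (groups == uniq[0]).to_numpy()
    if events.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), p


def _cox_derivatives(
    beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, score and information at beta."""
    order = np.argsort(-times, kind="mergesort")  # descending time
    x, times, events = x[order], times[order], events[order]
    eta = beta * x
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    loglik = score = info = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        # risk set for this time = all entries up to j-1 (times sorted desc)
        block = slice(i, j)
        d_idx = np.nonzero(events[block])[0] + i
        d = len(d_idx)
        if d > 0:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xbar = S1 / S0
            loglik += float(eta[d_idx].sum() - d * np.log(S0))
            score += float(x[d_idx].sum() - d * xbar)
            info += float(d * (S2 / S0 - xbar**2))
        i = j
    return loglik, score, info


def cox_univariate(
    expr: pd.Series,
    surv: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> dict:
    """Univariate Cox proportional hazards fit (Breslow ties, Newton-Raphson).

    Returns a dict with ``beta``, ``hazard_ratio``, ``se``, ``wald_z``,
    ``wald_p``, ``loglik``, ``iterations``, ``n``, ``n_events``.
    """
    surv = _validate_survival(surv)
    x = expr.reindex(surv.index).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("expression missing for some survival samples")
    n = len(x)
    n_events = int(surv["event"].sum())
    if n < 10:
        raise ValueError(f"cox_univariate needs >=10 samples, got {n}")
    if n_events < 3:
        raise ValueError(f"cox_univariate needs >=3 events, got {n_events}")
    if np.ptp(x) == 0:
        raise ValueError("expression is constant; Cox model undefined")

    times = surv["time"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=int)
    # center/scale internally for numerical stability; rescale beta after
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd
    beta = 0.0
    trace = []
    converged = False
    for it in range(1, max_iter + 1):
        loglik, score, info = _cox_derivatives(beta, xs, times, events)
        if info <= 0:
            raise CoxConvergenceError(
                "non-positive information; degenerate risk sets", trace
            )
        step = score / info
        beta += step
        trace.append((it, beta, loglik, score))
        if abs(beta) > 50:
            raise CoxConvergenceError(
                "monotone likelihood (perfect separation?): |beta| diverging",
                trace,
            )
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise CoxConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations", trace
        )
    loglik, _, info = _cox_derivatives(beta, xs, times, events)
    se_s = 1.0 / np.sqrt(info)
    beta_out = beta / sd
    se_out = se_s / sd
    z = beta_out / se_out
    return {
        "beta": float(beta_out),
        "hazard_ratio": float(np.exp(beta_out)),
        "se": float(se_out),
        "wald_z": float(z),
        "wald_p": float(2.0 * stats.norm.sf(abs(z))),
        "loglik": float(loglik),
        "iterations": len(trace),
        "n": n,
        "n_events": n_events,
    }


def cox_score_test(expr: pd.Series, surv: pd.DataFrame) -> float:
    """Score (Rao) chi-square at beta = 0; equals the log-rank statistic for a
    binary covariate with distinct event times."""
    surv = _validate_survival(surv)
    x = expr.reindex(surv.index).to_numpy(dtype=float)
    _, score, info = _cox_derivatives(
        0.0, x, surv["time"].to_numpy(dtype=float), surv["event"].to_numpy(dtype=int)
    )
    return float(score**2 / info)


@dataclass
class GeneSurvivalSummary:
    """Per-gene cross-cohort survival summary."""

    gene: str
    per_cohort: pd.DataFrame
    n_significant: int
    n_worse_when_high: int
    n_worse_when_low: int
    flagged_min_count: bool
    flagged_all_cohorts: bool


def _direction_label(curves: dict[str, pd.DataFrame], cox_beta: Optional[float]) -> str:
    """Worse-outcome direction from KM group medians, falling back to the Cox
    beta sign when a group median is undefined."""
    mh = median_survival(curves["high"])
    ml = median_survival(curves["low"])
    if np.isfinite(mh) and np.isfinite(ml) and mh != ml:
        return "worse_when_high" if mh < ml else "worse_when_low"
    if np.isfinite(mh) and not np.isfinite(ml):
        return "worse_when_high"
    if np.isfinite(ml) and not np.isfinite(mh):
        return "worse_when_low"
    if cox_beta is not None:
        return "worse_when_high" if cox_beta > 0 else "worse_when_low"
    return "worse_when_high"


def gene_cohort_result(expr: pd.Series, surv: pd.DataFrame) -> dict:
    """KM median-split + log-rank + univariate Cox for one gene in one cohort."""
    labels, curves = km_median_split(expr, surv)
    chi2, p = logrank_test(labels, surv)
    try:
        cox = cox_univariate(expr, surv)
        beta = cox["beta"]
    except (ValueError, CoxConvergenceError) as exc:
        logger.warning("Cox fit failed: %s", exc)
        cox = {"beta": np.nan, "hazard_ratio": np.nan, "wald_p": np.nan}
        beta = None
    return {
        "km_chi2": chi2,
        "km_p": p,
        "cox_beta": cox["beta"],
        "hazard_ratio": cox["hazard_ratio"],
        "wald_p": cox["wald_p"],
        "direction": _direction_label(curves, beta),
        "n_high": int((labels == "high").sum()),
        "n_low": int((labels == "low").sum()),
    }


def multi_cohort_summary(
    gene: str,
    cohorts: Sequence[tuple[str, pd.DataFrame]],
    alpha: float = 0.05,
    min_count: int = 3,
) -> GeneSurvivalSummary:
    """Count cohorts where the gene predicts survival (KM log-rank p < alpha),
    split by worse-outcome direction.

    ``cohorts`` is a sequence of ``(name, table)`` where each table carries
    ``time``, ``event`` and a column named after the gene.  Per-cohort
    failures are recorded as missing rows, not raised.
    """
    if not cohorts:
        raise ValueError("multi_cohort_summary needs >=1 cohort")
    rows = {}
    for name, table in cohorts:
        if gene not in table.columns:
            logger.warning("cohort %s lacks expression for %s; skipped", name, gene)
            continue
        try:
            rows[name] = gene_cohort_result(table[gene], table)
        except (ValueError, CoxConvergenceError) as exc:
            logger.warning("cohort %s failed for %s: %s", name, gene, exc)
    per_cohort = pd.DataFrame.from_dict(rows, orient="index")
    if len(per_cohort):
        sig = per_cohort["km_p"] < alpha
        worse_high = sig & (per_cohort["direction"] == "worse_when_high")
        worse_low = sig & (per_cohort["direction"] == "worse_when_low")
        n_sig, n_h, n_l = int(sig.sum()), int(worse_high.sum()), int(worse_low.sum())
    else:
        n_sig = n_h = n_l = 0
    return GeneSurvivalSummary(
        gene=gene,
        per_cohort=per_cohort,
        n_significant=n_sig,
        n_worse_when_high=n_h,
        n_worse_when_low=n_l,
        flagged_min_count=max(n_h, n_l) >= min_count,
        flagged_all_cohorts=len(cohorts) > 0
        and (n_h == len(cohorts) or n_l == len(cohorts)),
    )
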