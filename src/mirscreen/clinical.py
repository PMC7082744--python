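"""Clinical cohort analysis: expression contrast, Cox screening, KM curves.

For a cohort of primary and metastatic tumour samples with follow-up,
this module finds miRs down-regulated in metastases (Welch t-test on
log2 expression, BH-adjusted), dichotomizes expression at the median,
screens each miR with a univariate Cox proportional-hazards model
(Efron tie handling, Newton-Raphson on the partial likelihood) under
Bonferroni correction, and exports Kaplan-Meier curves.

Covariate orientation: the Cox indicator is 1 for *low* expression, so
HR > 1 reads "low expression carries worse survival".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOW = "low"
HIGH = "high"

COX_TOL = 1e-8
COX_MAX_ITER = 25


def clinical_de(
    expression: pd.DataFrame, tissue: pd.Series
) -> pd.DataFrame:
    """Per-miR primary-vs-metastasis contrast on log2 expression.

    logFC = mean(primary) - mean(metastasis): positive values mean the
    miR is down in metastases, matching the reporting convention in
    which down-regulated miRs carry positive fold changes.  Welch's
    two-sample t-test per miR with BH adjustment; a miR with zero
    variance in both groups gets p = 1 and a flag.
    """
    tissue = tissue.loc[expression.index]
    pri = expression[tissue == "primary"]
    met = expression[tissue == "metastasis"]
    if len(pri) < 3 or len(met) < 3:
        raise ValueError("need >= 3 samples per tissue group")
    logfc = pri.mean() - met.mean()
    rows = []
    for mir in expression.columns:
        a, b = pri[mir].to_numpy(), met[mir].to_numpy()
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            rows.append((mir, float(logfc[mir]), np.nan, 1.0, True))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((mir, float(logfc[mir]), float(t), float(p), False))
    out = pd.DataFrame(rows, columns=["mir", "logfc", "t", "pvalue", "zero_variance"])
    out["padj"] = stats.false_discovery_control(out["pvalue"], method="bh")
    return out


def dichotomize(values: pd.Series | np.ndarray) -> np.ndarray:
    """Median split: low = value <= median, high = value > median.

    The tie convention (values equal to the median go low) is fixed for
    determinism.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("cannot dichotomize: all values identical")
    med = np.median(v)
    return np.where(v > med, HIGH, LOW)


@dataclass
class CoxResult:
    coef: float
    hr: float
    se: float
    pvalue: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    separated: bool = False
    score_statistic: float = math.nan  # U(0)^2 / I(0), the log-rank statistic when untied


def _efron_quantities(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Efron partial log-likelihood, score and information at ``beta``.

    Risk sets are evaluated per distinct event time; tied events at a
    time are handled by Efron's average-subtraction of the tied set.
    """
    order = np.argsort(time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    eta = beta * xv
    w = np.exp(eta)
    # suffix sums over the risk set (t_i >= t_k)
    s0_suffix = np.cumsum(w[::-1])[::-1]
    s1_suffix = np.cumsum((w * xv)[::-1])[::-1]
    s2_suffix = np.cumsum((w * xv * xv)[::-1])[::-1]

    loglik = score = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = slice(i, j)
        d_idx = np.nonzero(d[tied])[0] + i
        dk = len(d_idx)
        if dk:
            s0 = s0_suffix[i]
            s1 = s1_suffix[i]
            s2 = s2_suffix[i]
            s0d = w[d_idx].sum()
            s1d = (w[d_idx] * xv[d_idx]).sum()
            s2d = (w[d_idx] * xv[d_idx] ** 2).sum()
            loglik += eta[d_idx].sum()
            for l in range(dk):
                f = l / dk
                phi0 = s0 - f * s0d
                phi1 = s1 - f * s1d
                phi2 = s2 - f * s2d
                loglik -= math.log(phi0)
                score += -phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
            score += (xv[d_idx]).sum()
        i = j
    return loglik, score, info


def cox_univariate(
    time: np.ndarray, event: np.ndarray, covariate: np.ndarray
) -> CoxResult:
    """Univariate Cox PH fit by Newton-Raphson on the Efron partial likelihood.

    Convergence at |delta beta| < 1e-8 within 25 iterations; SE from the
    observed information; two-sided Wald p.  A monotone likelihood
    (complete separation, the infinite-HR path) is flagged and the
    p-value falls back to the score test at beta = 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("need at least one observed event")
    if np.unique(x[event == 1]).size < 1 or np.unique(x).size < 2:
        raise ValueError("covariate constant: Cox model unidentifiable")

    _, u0, i0 = _efron_quantities(0.0, time, event, x)
    score_stat = u0**2 / i0 if i0 > 0 else math.nan

    beta = 0.0
    converged = False
    separated = False
    iterations = 0
    for iterations in range(1, COX_MAX_ITER + 1):
        _, u, info = _efron_quantities(beta, time, event, x)
        if info <= 0 or not math.isfinite(info):
            separated = True
            break
        step = u / info
        beta += step
        if abs(beta) > 15:
            separated = True
            break
        if abs(step) < COX_TOL:
            converged = True
            break
    _, _, info = _efron_quantities(beta, time, event, x)
    if separated or not converged or info <= 0:
        p = 2 * stats.norm.sf(math.sqrt(score_stat)) if math.isfinite(score_stat) else math.nan
        hr = math.inf if beta > 0 else 0.0
        return CoxResult(
            coef=math.copysign(math.inf, beta) if separated else beta,
            hr=hr,
            se=math.nan,
            pvalue=float(p),
            n=len(time),
            n_events=n_events,
            converged=False,
            iterations=iterations,
            separated=True,
            score_statistic=score_stat,
        )
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return CoxResult(
        coef=beta,
        hr=math.exp(beta),
        se=se,
        pvalue=float(p),
        n=len(time),
        n_events=n_events,
        converged=True,
        iterations=iterations,
        score_statistic=score_stat,
    )


def survival_screen(
    cohort: pd.DataFrame,
    mirs: list[str],
    subset: str = "primary",
) -> pd.DataFrame:
    """Median-split univariate Cox screen with Bonferroni correction.

    For each miR, the analysis subset (by default primary-tumour samples
    with follow-up) is dichotomized at its median expression, the Cox
    indicator codes 1 = low expression, and the Wald p is multiplied by
    the number of miRs tested (capped at 1).  Per-miR failures are
    recorded and the screen continues.
    """
    missing = [m for m in mirs if m not in cohort.columns]
    if missing:
        raise ValueError(f"miRs absent from cohort: {missing[:5]}")
    df = cohort if subset is None else cohort[cohort["type"] == subset]
    df = df[np.isfinite(df["time_months"])]
    m = len(mirs)
    rows = []
    for mir in mirs:
        try:
            labels = dichotomize(df[mir])
            x = (labels == LOW).astype(float)  # 1 = low expression
            res = cox_univariate(df["time_months"].to_numpy(), df["event"].to_numpy(), x)
            rows.append(
                (mir, res.hr, res.se, res.pvalue, min(1.0, res.pvalue * m),
                 res.n, res.n_events, res.converged, "")
            )
        except ValueError as exc:
            rows.append((mir, np.nan, np.nan, np.nan, np.nan, len(df), int(df["event"].sum()),
                         False, str(exc)))
    return pd.DataFrame(
        rows,
        columns=["mir", "hr", "se", "pvalue", "p_bonferroni", "n", "events", "converged", "error"],
    )


def km_estimate(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> pd.DataFrame:
    """Kaplan-Meier product-limit curves per group.

    Each curve starts at S(0) = 1, is non-increasing, and drops only at
    observed event times.  Returns a long table (group, time, survival).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    rows = []
    for g in pd.unique(group):
        mask = group == g
        if not mask.any():
            continue
        t, d = time[mask], event[mask]
        order = np.argsort(t, kind="stable")
        t, d = t[order], d[order]
        s = 1.0
        rows.append((g, 0.0, 1.0))
        at_risk = len(t)
        for tk in np.unique(t):
            sel = t == tk
            dk = int(d[sel].sum())
            if dk > 0:
                s *= 1.0 - dk / at_risk
                rows.append((g, float(tk), s))
            at_risk -= int(sel.sum())
    return pd.DataFrame(rows, columns=["group", "time", "survival"])
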