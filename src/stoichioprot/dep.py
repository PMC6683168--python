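"""Differential protein expression screening.

Per-protein case/control comparison via a log2 score ratio and an
empirical-Bayes moderated two-sample t-statistic: each protein's pooled
sample variance s^2 (residual df d) is shrunk toward a prior (d0, s0^2)
estimated across the proteome,

    s~^2 = (d0*s0^2 + d*s^2) / (d0 + d),

and the statistic is referred to a t distribution with d0 + d degrees of
freedom.  With d0 = 0 this reduces exactly to the ordinary pooled t-test;
with d0 -> inf the variance is the prior alone.  Calls combine a fold
gate (|log2 ratio| > 1), a p-value gate (alpha) and a BH-FDR gate (Q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DEPResult:
    protein_id: str
    log2_ratio: float
    statistic: float
    p_value: float
    q_value: float
    call: str  # up | down | none


def log2_ratio(
    case_mean: float, control_mean: float, pseudocount: float = 0.1
) -> float:
    """log2((case + c) / (control + c)) with pseudocount ``c`` guarding zeros."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    num = case_mean + pseudocount
    den = control_mean + pseudocount
    if num <= 0 or den <= 0:
        raise ValueError(
            "undefined ratio: both means are zero with a zero pseudocount"
        )
    return math.log2(num / den)


def _pooled_variance(case: np.ndarray, control: np.ndarray) -> tuple[float, int]:
    n1, n2 = len(case), len(control)
    d = (n1 - 1) + (n2 - 1)
    if d <= 0:
        raise ValueError("need at least 2 values across groups beyond the means")
    ss = 0.0
    if n1 > 1:
        ss += float(np.sum((case - case.mean()) ** 2))
    if n2 > 1:
        ss += float(np.sum((control - control.mean()) ** 2))
    return ss / d, d


def moderated_t(
    case: Sequence[float],
    control: Sequence[float],
    d0: float = 0.0,
    s0_sq: float = 0.0,
) -> tuple[float, float]:
    """Moderated two-sample t on group means with shrunken variance.

    Returns ``(statistic, two_sided_p)``.  ``d0=0`` gives the ordinary
    pooled t-test.  If the shrunken variance is exactly zero the result is
    degenerate: equal means give (0, 1); different means give
    (signed inf, 0).
    """
    case = np.asarray(case, dtype=np.float64)
    control = np.asarray(control, dtype=np.float64)
    if len(case) < 1 or len(control) < 1:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(case)) and np.all(np.isfinite(control))):
        raise ValueError("non-finite values in input")
    s_sq, d = _pooled_variance(case, control)
    if math.isinf(d0):
        s_tilde, df = s0_sq, math.inf
    else:
        s_tilde = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df = d0 + d
    diff = float(case.mean() - control.mean())
    se_sq = s_tilde * (1.0 / len(case) + 1.0 / len(control))
    if se_sq <= 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(se_sq)
    if math.isinf(df):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(min(p, 1.0))


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton with monotone update)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(
    variances: Sequence[float], df: int
) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Models each sample variance as s^2 | sigma^2 ~ sigma^2 * chi2_d / d
    with sigma^2 ~ d0*s0^2 / chi2_d0, and matches the mean and variance of
    log s^2 to the implied digamma/trigamma moments.  Returns d0 = inf when
    the observed dispersion of log s^2 is at or below the sampling minimum.
    Requires >= 10 positive, finite variances.
    """
    v = np.asarray(variances, dtype=np.float64)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) < 10:
        raise ValueError(
            f"need >= 10 positive variances to fit a prior (got {len(v)}); "
            "use d0=0 for an unmoderated screen"
        )
    z = np.log(v)
    if float(np.var(z)) < 1e-14:
        return math.inf, float(v[0])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) * (1.0 - 1.0 / len(e))  # limma's n-scaling
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_deps(
    protein_ids: Sequence[str],
    log2_ratios: Sequence[float],
    statistics: Sequence[float],
    p_values: Sequence[float],
    q_values: Sequence[float],
    alpha: float = 0.05,
    max_q: float = 0.01,
    lfc: float = 1.0,
) -> list[DEPResult]:
    """Combine fold, p and q gates into up/down/none calls."""
    arrays = [log2_ratios, statistics, p_values, q_values]
    if any(len(a) != len(protein_ids) for a in arrays):
        raise ValueError("all input vectors must have the same length")
    results = []
    for pid, lr, t, p, q in zip(protein_ids, *arrays):
        if p < alpha and q <= max_q and lr > lfc:
            call = "up"
        elif p < alpha and q <= max_q and lr < -lfc:
            call = "down"
        else:
            call = "none"
        results.append(DEPResult(pid, float(lr), float(t), float(p), float(q), call))
    return results


def screen_deps(
    matrix: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    alpha: float = 0.05,
    max_q: float = 0.01,
    lfc: float = 1.0,
    pseudocount: float = 0.1,
    prior_d0: float | None = None,
    prior_s0_sq: float | None = None,
) -> pd.DataFrame:
    """Full screen: log2 ratios + moderated t + BH-FDR + calls.

    ``matrix`` is the protein x sample score matrix (NaN = missing).
    Proteins missing in an entire group, or with fewer than 2 observed
    values overall beyond the two means, are dropped (counted in the
    ``n_dropped`` attribute of the result).  When ``prior_d0`` is None the
    prior is estimated from proteins at the modal residual df.
    """
    case_m = matrix[list(case_samples)].to_numpy(dtype=np.float64)
    ctrl_m = matrix[list(control_samples)].to_numpy(dtype=np.float64)
    pids = list(matrix.index)

    usable, s_sq_list, d_list = [], [], []
    per_protein: list[tuple[str, np.ndarray, np.ndarray]] = []
    for i, pid in enumerate(pids):
        cv = case_m[i][np.isfinite(case_m[i])]
        gv = ctrl_m[i][np.isfinite(ctrl_m[i])]
        if len(cv) == 0 or len(gv) == 0 or (len(cv) - 1) + (len(gv) - 1) < 1:
            continue
        usable.append(pid)
        per_protein.append((pid, cv, gv))
        s_sq, d = _pooled_variance(cv, gv)
        s_sq_list.append(s_sq)
        d_list.append(d)

    if not per_protein:
        raise ValueError("no proteins with enough observations in both groups")

    if prior_d0 is None:
        d_arr = np.asarray(d_list)
        modal_d = int(stats.mode(d_arr, keepdims=False).mode)
        var_at_modal = [s for s, d in zip(s_sq_list, d_list) if d == modal_d]
        try:
            d0, s0_sq = estimate_prior(var_at_modal, modal_d)
        except ValueError:
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = prior_d0
        s0_sq = prior_s0_sq if prior_s0_sq is not None else 0.0

    ratios, tstats, pvals = [], [], []
    for pid, cv, gv in per_protein:
        ratios.append(log2_ratio(float(cv.mean()), float(gv.mean()), pseudocount))
        t, p = moderated_t(cv, gv, d0=d0, s0_sq=s0_sq)
        tstats.append(t)
        pvals.append(p)
    qvals = bh_fdr(pvals)
    calls = call_deps(usable, ratios, tstats, pvals, qvals, alpha, max_q, lfc)
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in calls],
            "log2_ratio": [r.log2_ratio for r in calls],
            "statistic": [r.statistic for r in calls],
            "p_value": [r.p_value for r in calls],
            "q_value": [r.q_value for r in calls],
            "call": [r.call for r in calls],
        }
    ).set_index("protein_id")
    df.attrs["prior_d0"] = d0
    df.attrs["prior_s0_sq"] = s0_sq
    df.attrs["n_dropped"] = len(pids) - len(usable)
    return df
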