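"""Rank-based comparison of element contents between protein groups.

The headline statistic is the percent difference of group mean contents,
100*(mean_a - mean_b)/mean_b, with significance from the two-sample
Mann-Whitney U (Wilcoxon rank-sum) test.  Carbon is always computed
alongside the element of interest as a composition-analysis control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

EXACT_LIMIT = 12  # total sample size up to which the null is enumerated


@dataclass
class GroupComparisonResult:
    element: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    percent_difference: float
    u_statistic: float
    p_value: float


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #{(i,j): a_i > b_j} + 0.5 * #ties, via midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def _exact_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Enumerate all C(n, n_a) group assignments of the pooled values.

    Handles ties exactly (permutation null of the U statistic).
    """
    n_a = len(a)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum() - offset)
    us = np.array(
        [sum(ranks[list(idx)]) - offset for idx in combinations(range(len(pooled)), n_a)]
    )
    total = len(us)
    eps = 1e-9
    p_le = np.sum(us <= u_obs + eps) / total
    p_ge = np.sum(us >= u_obs - eps) / total
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return u_obs, float(p)


def _excess_kurtosis(n_a: int, n_b: int) -> float:
    """Exact excess kurtosis of the tie-free U null distribution."""
    n = n_a + n_b
    return -1.2 * (n_a**2 + n_b**2 + n_a * n_b + n) / (n_a * n_b * (n + 1))


def _edgeworth_cdf(z: float, gamma2: float) -> float:
    """P(U <= u) with a one-term kurtosis (Edgeworth) correction.

    The U null is symmetric (skewness 0) but platykurtic; the correction
    term phi(z)*(gamma2/24)*(z^3 - 3z) repairs the tails at small n.
    """
    return float(
        stats.norm.cdf(z) - stats.norm.pdf(z) * (gamma2 / 24.0) * (z**3 - 3.0 * z)
    )


def _approx_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Edgeworth-corrected normal approximation with tie-corrected variance
    and continuity correction."""
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    u = _u_statistic(a, b)
    mu = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all pooled values identical: no evidence either way
        return u, 1.0
    sd = math.sqrt(var)
    g2 = _excess_kurtosis(n_a, n_b)
    # tail probabilities with continuity correction on the lattice of U
    p_le = max(min(_edgeworth_cdf((u + 0.5 - mu) / sd, g2), 1.0), 0.0)
    p_ge = max(min(1.0 - _edgeworth_cdf((u - 0.5 - mu) / sd, g2), 1.0), 0.0)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return u, float(p)


def mann_whitney_u(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test (unpaired Wilcoxon rank-sum).

    ``U`` counts pairs with a > b plus half the ties.  ``method='auto'``
    enumerates the exact permutation null when n_a + n_b <= 12 and falls
    back to the tie-corrected normal approximation otherwise; ``'exact'``
    and ``'approx'`` force a path.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method == "auto":
        method = "exact" if len(a) + len(b) <= EXACT_LIMIT else "approx"
    if method == "exact":
        return _exact_p(a, b, alternative)
    if method == "approx":
        return _approx_p(a, b, alternative)
    raise ValueError(f"unknown method {method!r}")


def percent_difference(mean_a: float, mean_b: float) -> float:
    """100 * (mean_a - mean_b) / mean_b; reported to one decimal in summaries."""
    if mean_b <= 0:
        raise ValueError("reference mean (mean_b) must be positive")
    return 100.0 * (mean_a - mean_b) / mean_b


def compare_groups(
    contents: Mapping[str, Mapping[str, float]],
    group_a: set[str] | Sequence[str],
    group_b: set[str] | Sequence[str],
    element: str = "O",
    label_a: str = "group_a",
    label_b: str = "group_b",
    control_element: str | None = "C",
) -> list[GroupComparisonResult]:
    """Compare element contents of two disjoint protein groups.

    ``contents`` maps protein id -> {element -> content}.  The carbon
    control comparison is always appended unless ``control_element`` is
    None or equals ``element``.  Overlapping groups and ids without a
    profile are errors.
    """
    set_a, set_b = set(group_a), set(group_b)
    overlap = set_a & set_b
    if overlap:
        raise ValueError(
            f"groups overlap ({len(overlap)} shared ids, e.g. "
            f"{sorted(overlap)[:3]}); a protein cannot be in both"
        )
    missing = [pid for pid in set_a | set_b if pid not in contents]
    if missing:
        raise ValueError(f"ids without element profiles: {sorted(missing)[:5]}")
    elements = [element]
    if control_element and control_element != element:
        elements.append(control_element)
    results = []
    ids_a, ids_b = sorted(set_a), sorted(set_b)
    for elem in elements:
        va = np.array([contents[pid][elem] for pid in ids_a])
        vb = np.array([contents[pid][elem] for pid in ids_b])
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        u, p = mann_whitney_u(va, vb)
        # percent difference is only defined against a positive reference
        pct = percent_difference(mean_a, mean_b) if mean_b > 0 else math.nan
        results.append(
            GroupComparisonResult(
                element=elem,
                group_a=label_a,
                group_b=label_b,
                n_a=len(va),
                n_b=len(vb),
                mean_a=mean_a,
                mean_b=mean_b,
                percent_difference=pct,
                u_statistic=u,
                p_value=p,
            )
        )
    return results
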