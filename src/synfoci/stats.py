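"""Nonparametric two-group statistics and per-cell report helpers.

Two tests carry every comparison in the pipeline: the Mann-Whitney U
(Wilcoxon rank-sum) test for unpaired per-cell measurements across
conditions, and the Wilcoxon signed-rank test for paired within-cell
comparisons (e.g. foci vs lamellar surround).  Both are implemented with
an exact enumeration path at small sample sizes and a tie- and
continuity-corrected normal approximation otherwise; all p-values are
two-sided.  Summaries are mean ± SEM (SD with the n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

#: exact Mann-Whitney enumeration is used up to this pooled sample size
MWU_EXACT_MAX_N = 12
#: exact signed-rank enumeration is used up to this many nonzero pairs
WILCOXON_EXACT_MAX_N = 15


@dataclass
class GroupComparison:
    """Outcome of one two-group test."""

    statistic_name: str   # "U" or "W"
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str           # "exact" or "normal"
    group1: str = ""
    group2: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("each group needs at least one observation")


def _rank(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _normal_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def _edgeworth_sf(z: float, gamma2: float) -> float:
    """Upper tail of a symmetric lattice statistic, normal term plus the
    Edgeworth kurtosis correction (both rank statistics are platykurtic,
    so the plain normal overshoots moderate tails)."""
    phi = np.exp(-0.5 * z * z) / sqrt(2.0 * np.pi)
    sf = _normal_sf(z) + gamma2 / 24.0 * (z**3 - 3.0 * z) * phi
    return min(max(sf, 0.0), 1.0)


def mann_whitney_u(x, y, method: str = "auto") -> GroupComparison:
    """Mann-Whitney U test (two-sided).

    The statistic is U for the first sample with half credit for ties, so
    U_x + U_y = n1*n2.  With ``method="auto"`` the p-value is computed by
    full enumeration of the C(n1+n2, n1) rank labelings when the pooled
    sample is small (<= 12) and tie-free, and by the tie- and
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _rank(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if method == "auto":
        method = "exact" if (n1 + n2 <= MWU_EXACT_MAX_N and not has_ties) else "normal"
    if method == "exact":
        mu = n1 * n2 / 2.0
        dev = abs(u1 - mu)
        total = comb(n1 + n2, n1)
        count = 0
        all_ranks = np.arange(1, n1 + n2 + 1)
        for subset in combinations(range(n1 + n2), n1):
            u = all_ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        p = count / total
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / sqrt(var)
            gamma2 = -1.2 * (n1**2 + n2**2 + n1 * n2 + n1 + n2) / (n1 * n2 * (n + 1))
            p = min(1.0, 2.0 * _edgeworth_sf(max(z, 0.0), gamma2))
        method = "normal"
    return GroupComparison("U", u1, max(p, np.finfo(float).tiny), n1, n2, method)


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank test by sign enumeration.

    ``ranks2`` are the (tie-averaged) ranks doubled so they are integers;
    ``w2`` is the doubled observed positive-rank sum.  Enumerates the 2^n
    equiprobable sign patterns via a subset-sum count.
    """
    ranks2 = np.asarray(np.round(ranks2), dtype=int)
    total2 = int(ranks2.sum())
    # DP over achievable positive-rank sums: counts[s] = number of sign
    # patterns whose positive ranks sum to s (doubled units)
    counts = np.zeros(total2 + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total2 + 1 - r]
        counts = counts + shifted
    mu = total2 / 2.0
    dev = abs(w2 - mu)
    sums = np.arange(total2 + 1)
    n_extreme = int(counts[np.abs(sums - mu) >= dev - 1e-9].sum())
    return n_extreme / float(2 ** len(ranks2))


def wilcoxon_signed_rank(x, y, method: str = "auto") -> GroupComparison:
    """Wilcoxon signed-rank test for paired samples (two-sided).

    Zero differences are dropped; W is the sum of the ranks of the
    positive differences among the ranked |d|.  Exact sign enumeration is
    used for up to 15 nonzero pairs, otherwise the tie- and
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = _rank(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if method == "auto":
        method = "exact" if n <= WILCOXON_EXACT_MAX_N else "normal"
    if method == "exact":
        p = _signed_rank_exact_p(ranks * 2.0, w_pos * 2.0)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w_pos - mu) - 0.5) / sqrt(var)
            gamma2 = -2.4 * (3 * n**2 + 3 * n - 1) / (n * (n + 1) * (2 * n + 1))
            p = min(1.0, 2.0 * _edgeworth_sf(max(z, 0.0), gamma2))
        method = "normal"
    return GroupComparison("W", w_pos, max(p, np.finfo(float).tiny), n, n, method)


def format_p(p: float, floor: float = 1e-6) -> str:
    """Human-readable p-value: below ``floor`` report '< floor'."""
    return f"< {floor:g}" if p < floor else f"{p:.3g}"


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error (SD with n-1 denominator over sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    sem = float(v.std(ddof=1) / sqrt(len(v))) if len(v) > 1 else 0.0
    return float(v.mean()), sem


def compare_groups(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    pairs: list[tuple[str, str]],
    paired: bool = False,
) -> pd.DataFrame:
    """Run the appropriate two-group test for each requested pairing.

    Emits one row per comparison with columns matching the report layout:
    ``measure, group1, group2, n1, n2, statistic, p_two_sided, method``.
    """
    rows = []
    for g1, g2 in pairs:
        x = table.loc[table[group_col] == g1, value_col].to_numpy()
        y = table.loc[table[group_col] == g2, value_col].to_numpy()
        res = (
            wilcoxon_signed_rank(x, y) if paired else mann_whitney_u(x, y)
        )
        rows.append(
            {
                "measure": value_col,
                "group1": g1,
                "group2": g2,
                "n1": res.n1,
                "n2": res.n2,
                "statistic": res.statistic,
                "p_two_sided": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
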