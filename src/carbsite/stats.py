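"""Nonparametric statistics implemented from their rank definitions.

These are the tests used downstream of quantification: Spearman's rho for
the carbamylation-degree/MPO-activity association, the Mann-Whitney U test
for independent groups, Wilcoxon's matched-pairs signed-rank test for
paired samples, and the median fold change for reporting group contrasts.

Ranks, tie handling, U/W statistics and exact small-sample enumeration are
computed here directly; only distribution functions (normal, t) come from
scipy.  Conventions are fixed so every p-value is reproducible:

* mid-ranks for ties throughout;
* two-sided p-values by default;
* exact enumeration for small samples (pooled n <= 12 for Mann-Whitney,
  n <= 12 non-zero pairs for Wilcoxon), defined as the null probability of
  a statistic at least as far from its null mean as observed;
* normal approximation with tie-corrected variance and a 0.5 continuity
  correction otherwise;
* Spearman p from the t approximation t = rho*sqrt((n-2)/(1-rho^2)).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

__all__ = [
    "COHORT_GROUPS",
    "midranks",
    "spearman_rho",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "median_fold_change",
    "read_cohort_table",
    "correlation_report",
]

COHORT_GROUPS = ("RA-SF", "RA-plasma", "HC-plasma", "RA-blood-NE", "HC-blood-NE")

EXACT_ENUMERATION_LIMIT = 12


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _drop_missing_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with a two-sided t-approximation p.

    Missing pairs are dropped pairwise; needs n >= 3 complete pairs and
    non-constant ranks on both sides.
    """
    x, y = _drop_missing_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx, ry = midranks(x), midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero rank variance: all values tied")
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t_stat = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * t_dist.sf(abs(t_stat), df=n - 2)
    return rho, float(min(p, 1.0))


def _u_statistic(pooled_ranks: np.ndarray, idx_a: Sequence[int], n_a: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2)


def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U of sample ``a`` with mid-ranks for ties.

    Exact permutation enumeration when the pooled size is <= 12 (two-sided
    p is the null probability of a U at least as far from its mean as
    observed); otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    mu = n_a * n_b / 2

    n = n_a + n_b
    if n <= EXACT_ENUMERATION_LIMIT:
        hits = 0
        total = 0
        obs_dev = abs(u_obs - mu)
        for idx in combinations(range(n), n_a):
            u = _u_statistic(ranks, idx, n_a)
            total += 1
            if alternative == "two-sided":
                hits += abs(u - mu) >= obs_dev - 1e-12
            elif alternative == "greater":
                hits += u >= u_obs - 1e-12
            elif alternative == "less":
                hits += u <= u_obs + 1e-12
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        return u_obs, hits / total

    # tie-corrected normal approximation
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    sigma2 = n_a * n_b / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_obs, 1.0
    sigma = np.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = 2 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        p = norm.sf((u_obs - mu - 0.5) / sigma)
    elif alternative == "less":
        p = norm.cdf((u_obs - mu + 0.5) / sigma)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return u_obs, float(min(p, 1.0))


def wilcoxon_signed_rank(
    pairs: Iterable[tuple[float, float]] | Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test.

    ``pairs`` is either a sequence of (x, y) pairs or a 1-d array of
    differences.  Zero differences are dropped; |d| is mid-ranked; the
    statistic W is the sum of ranks of positive differences.  Exact sign
    enumeration for <= 12 non-zero pairs, normal approximation otherwise.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim == 2:
        if arr.shape[1] != 2:
            raise ValueError("pairs must be (x, y) tuples or differences")
        d = arr[:, 0] - arr[:, 1]
    else:
        d = arr
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no non-zero differences")
    ranks = midranks(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total_rank = float(ranks.sum())
    mu = total_rank / 2

    if n <= EXACT_ENUMERATION_LIMIT:
        hits = 0
        obs_dev = abs(w_obs - mu)
        for mask in range(1 << n):
            w = sum(ranks[i] for i in range(n) if mask >> i & 1)
            if alternative == "two-sided":
                hits += abs(w - mu) >= obs_dev - 1e-12
            elif alternative == "greater":
                hits += w >= w_obs - 1e-12
            elif alternative == "less":
                hits += w <= w_obs + 1e-12
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        return w_obs, hits / (1 << n)

    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - float((counts**3 - counts).sum()) / 48
    sigma = np.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(w_obs - mu) - 0.5) / sigma
        p = 2 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        p = norm.sf((w_obs - mu - 0.5) / sigma)
    elif alternative == "less":
        p = norm.cdf((w_obs - mu + 0.5) / sigma)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_obs, float(min(p, 1.0))


def median_fold_change(a, b) -> float:
    """median(a) / median(b); the reporting statistic for group contrasts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    med_b = float(np.median(b))
    if med_b == 0:
        raise ValueError("median of the denominator group is zero")
    return float(np.median(a)) / med_b


def read_cohort_table(path) -> pd.DataFrame:
    """Cohort table: sample_id, group, mpo_activity (ng/mL),
    neutrophil_count (cells/mL), carb_degree (percent)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "mpo_activity", "neutrophil_count", "carb_degree"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s) {sorted(missing)}")
    bad = set(df["group"]) - set(COHORT_GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    for col in ("mpo_activity", "neutrophil_count", "carb_degree"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")
    return df


def correlation_report(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]] = (
        ("carb_degree_vs_mpo", "carb_degree", "mpo_activity"),
        ("mpo_vs_neutrophils", "mpo_activity", "neutrophil_count"),
        ("carb_degree_vs_neutrophils", "carb_degree", "neutrophil_count"),
    ),
    group: str = "RA-SF",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation panel within one cohort group.

    The significance flag annotates p < alpha; it filters nothing.
    """
    sub = cohort[cohort["group"] == group]
    rows = []
    for name, xcol, ycol in pairs:
        x, y = _drop_missing_pairs(sub[xcol], sub[ycol])
        rho, p = spearman_rho(x, y)
        rows.append(
            {
                "pair": name,
                "group": group,
                "n": len(x),
                "rho": round(rho, 4),
                "p_value": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=["pair", "group", "n", "rho", "p_value", "significant"])
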