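"""Group-comparison statistics: ROUT outlier screening, two-group tests,
one-way ANOVA with Sidak-corrected pairwise comparisons.

The layer mirrors common biostatistics practice for small animal-study
groups: outliers are screened per group by the ROUT procedure (robust fit +
FDR-controlled residual test with parameter Q) before testing; means are
compared with a two-sided t-test (summary mean +/- SD), medians with the
Mann-Whitney U test (summary median +/- IQR; exact enumeration at small n),
and three or more groups with one-way ANOVA followed by pairwise comparisons
adjusted as p_adj = 1 - (1 - p)^m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

# ---------------------------------------------------------------------------
# ROUT outlier screening (constant-location model)


def rout_outliers(values, q: float = 0.01) -> np.ndarray:
    """Indices of outliers by the ROUT method for a single sample.

    The location is fitted robustly (median); the robust scale (RSDR) is the
    68.27th percentile of the absolute residuals with the small-sample
    correction n/(n-1). Each residual is converted to a two-sided t-tail
    probability (df = n-1) and candidates are flagged outside-in with a
    false-discovery-rate criterion at Q (Benjamini-Hochberg over the n
    residual p-values). With n < 4 no screening is attempted.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        warnings.warn("ROUT needs n >= 4; no outliers flagged")
        return np.array([], dtype=int)
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return np.array([], dtype=int)
    p = 2.0 * sps.t.sf(np.abs(resid) / rsdr, df=n - 1)
    order = np.argsort(p)
    thresh = q * (np.arange(1, n + 1) / n)
    passed = p[order] <= thresh
    if not passed.any():
        return np.array([], dtype=int)
    kmax = int(np.max(np.nonzero(passed)[0]))
    return np.sort(order[: kmax + 1])


# ---------------------------------------------------------------------------
# summaries


def summarize(values, style: str) -> dict:
    x = np.asarray(values, dtype=float)
    if style == "mean ± SD":
        return {"center": float(np.mean(x)),
                "spread": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
                "style": style, "n": int(x.size)}
    if style == "median ± IQR":
        return {"center": float(np.median(x)), "spread": float(sps.iqr(x)),
                "style": style, "n": int(x.size)}
    raise ValueError(f"unknown summary style {style!r}")


# ---------------------------------------------------------------------------
# Mann-Whitney U (exact by enumeration at small n)


def _mwu_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def mannwhitney_exact_p(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration (handles ties).

    Enumerates all C(n1+n2, n1) assignments of the pooled mid-ranks and
    returns 2*min(P(U <= u), P(U >= u)) capped at 1, together with u.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _mwu_statistic(ranks[:n1], n1)
    total = comb(n1 + n2, n1)
    le = ge = 0
    for idx in combinations(range(n1 + n2), n1):
        u = _mwu_statistic(ranks[list(idx)], n1)
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(p, 1.0), u_obs


@dataclass
class GroupComparison:
    group_labels: tuple
    n_per_group: tuple
    test: str
    statistic: float
    p_value: float
    summaries: dict
    outliers_removed: dict = field(default_factory=dict)
    rout_q: float | None = None
    pairwise: dict | None = None   # ANOVA: {(i, j): (raw p, adjusted p)}

    def __post_init__(self):
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


EXACT_MW_MAX_N = 20


def compare_two(
    group_a,
    group_b,
    *,
    test: str = "t",
    labels: tuple = ("A", "B"),
    rout_q: float | None = None,
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``test='t'`` compares means (summaries mean +/- SD);
    ``test='mannwhitney'`` compares medians (summaries median +/- IQR), using
    exact enumeration when the combined n is <= 20 and the normal
    approximation with tie correction otherwise. When ``rout_q`` is given,
    ROUT screening runs per group first and flagged values are removed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    removed = {}
    if rout_q is not None:
        for name, arr in zip(labels, (a, b)):
            idx = rout_outliers(arr, q=rout_q)
            if idx.size:
                removed[name] = idx.tolist()
        a = np.delete(a, removed.get(labels[0], []))
        b = np.delete(b, removed.get(labels[1], []))

    if test == "t":
        res = sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        style = "mean ± SD"
    elif test == "mannwhitney":
        if a.size + b.size <= EXACT_MW_MAX_N:
            p, stat = mannwhitney_exact_p(a, b)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        style = "median ± IQR"
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        group_labels=tuple(labels),
        n_per_group=(a.size, b.size),
        test="t-test" if test == "t" else "Mann–Whitney U",
        statistic=stat,
        p_value=p,
        summaries={labels[0]: summarize(a, style), labels[1]: summarize(b, style)},
        outliers_removed=removed,
        rout_q=rout_q,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA + Sidak


def sidak_adjust(p_raw, m: int) -> np.ndarray:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m (monotone, <= 1)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p_raw, dtype=float)) ** m


def anova_sidak(
    groups: dict | list,
    *,
    rout_q: float | None = None,
) -> GroupComparison:
    """One-way ANOVA omnibus plus pairwise Sidak-adjusted comparisons.

    Pairwise statistics use the pooled ANOVA error (t on df = N - k); the
    adjustment is 1 - (1 - p_raw)^m over the m = k(k-1)/2 comparisons.
    Requires at least three groups (use :func:`compare_two` for two).
    """
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
        labels = tuple(f"group{i + 1}" for i in range(len(arrays)))
    if len(arrays) < 3:
        raise ValueError("ANOVA needs >= 3 groups; use compare_two for two groups")
    removed = {}
    if rout_q is not None:
        cleaned = []
        for name, arr in zip(labels, arrays):
            idx = rout_outliers(arr, q=rout_q)
            if idx.size:
                removed[name] = idx.tolist()
            cleaned.append(np.delete(arr, idx))
        arrays = cleaned
    for arr in arrays:
        if arr.size < 2:
            raise ValueError("each group needs n >= 2")

    f_stat, p_omni = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_err = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err

    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    pairwise = {}
    for i, j in pairs:
        ai, aj = arrays[i], arrays[j]
        if mse == 0:
            t = np.inf if ai.mean() != aj.mean() else 0.0
        else:
            t = (ai.mean() - aj.mean()) / np.sqrt(mse * (1 / ai.size + 1 / aj.size))
        p_raw = float(2.0 * sps.t.sf(abs(t), df=df_err)) if np.isfinite(t) else 0.0
        pairwise[(labels[i], labels[j])] = (p_raw, float(sidak_adjust(p_raw, m)))

    return GroupComparison(
        group_labels=labels,
        n_per_group=tuple(a.size for a in arrays),
        test="one-way ANOVA + Šidák",
        statistic=float(f_stat),
        p_value=float(p_omni),
        summaries={lab: summarize(a, "mean ± SD") for lab, a in zip(labels, arrays)},
        outliers_removed=removed,
        rout_q=rout_q,
        pairwise=pairwise,
    )
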