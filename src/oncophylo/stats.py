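"""Cohort statistics implemented from their definitions.

Kruskal-Wallis, the two-sample Kolmogorov-Smirnov test, the Pearson
correlation and Benjamini-Hochberg FDR control are written out from first
principles here (ranking, ECDF scan, moment formulas, step-up rule) so that
each can be audited line-by-line and cross-checked against independent
implementations in the test-suite. Only distribution functions (χ²,
Student t, the Kolmogorov tail) come from scipy.

Also provides the lifespan-scaled age-at-death comparison: within each clade,
ages at death of tumour-bearing vs tumour-free animals are divided by the
species' reference lifespan and compared with the KS test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .records import CLASS_BENIGN, CLASS_MALIGNANT, classify_record

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p: float
    n: tuple[int, ...]


@dataclass(frozen=True)
class FdrResult:
    raw: np.ndarray
    adjusted: np.ndarray
    reject: np.ndarray
    q: float


def _average_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (ties share the average of the ranks they span)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def kruskal_wallis(groups, exact: bool = False) -> TestResult:
    """Kruskal-Wallis H across ≥2 groups with the tie correction.

    H = 12/(N(N+1)) Σ n_g (R̄_g − (N+1)/2)², divided by
    1 − Σ(t³−t)/(N³−N) over tie groups; p from χ² with (groups−1) df.
    With ``exact=True`` (feasible only for tiny pooled n) the p-value is the
    permutation tail probability of H over all group relabelings.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    N = len(pooled)

    def h_stat(pool: np.ndarray) -> float:
        ranks = _average_ranks(pool)
        h = 0.0
        start = 0
        for ng in sizes:
            rbar = ranks[start : start + ng].mean()
            h += ng * (rbar - (N + 1) / 2.0) ** 2
            start += ng
        h *= 12.0 / (N * (N + 1))
        _, counts = np.unique(pool, return_counts=True)
        tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
        if tie == 0.0:
            return 0.0
        return h / tie

    H = h_stat(pooled)
    df = len(groups) - 1
    if H == 0.0 and np.all(pooled == pooled[0]):
        p = 1.0
    elif exact:
        p = _permutation_pvalue(pooled, sizes, h_stat, H)
    else:
        p = float(sps.chi2.sf(H, df))
    return TestResult("kruskal_wallis", float(H), p, tuple(int(s) for s in sizes))


def _permutation_pvalue(pooled, sizes, stat_fn, observed, limit=2_000_000) -> float:
    """Exact permutation tail probability by full enumeration of assignments."""
    N = len(pooled)
    total = math.factorial(N)
    for s in sizes:
        total //= math.factorial(s)
    if total > limit:
        raise ValueError(f"exact permutation infeasible: {total} arrangements")
    idx = np.arange(N)
    count = 0
    n_arr = 0
    # enumerate assignments of indices to ordered groups
    def assignments(remaining, size_list):
        if not size_list:
            yield []
            return
        s = size_list[0]
        for combo in itertools.combinations(remaining, s):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, size_list[1:]):
                yield [list(combo)] + tail

    for assign in assignments(list(idx), list(sizes)):
        perm = np.concatenate([pooled[g] for g in assign])
        if stat_fn(perm) >= observed - 1e-12:
            count += 1
        n_arr += 1
    return count / n_arr


def ks_two_sample(x, y, exact: bool = False) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup|ECDF_x − ECDF_y|.

    The statistic is computed by scanning the pooled order statistics; the
    p-value uses the asymptotic Kolmogorov tail at √(mn/(m+n))·D, or full
    permutation enumeration with ``exact=True``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")

    def d_stat(xs: np.ndarray, ys: np.ndarray) -> float:
        grid = np.concatenate([xs, ys])
        cdf_x = np.searchsorted(xs, grid, side="right") / len(xs)
        cdf_y = np.searchsorted(ys, grid, side="right") / len(ys)
        return float(np.max(np.abs(cdf_x - cdf_y)))

    D = d_stat(x, y)
    if exact:
        pooled = np.concatenate([x, y])
        total = math.comb(m + n, m)
        if total > 2_000_000:
            raise ValueError(f"exact permutation infeasible: {total} arrangements")
        count = 0
        idx = range(m + n)
        for combo in itertools.combinations(idx, m):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(combo)] = True
            d = d_stat(np.sort(pooled[mask]), np.sort(pooled[~mask]))
            if d >= D - 1e-12:
                count += 1
        p = count / total
    else:
        en = math.sqrt(m * n / (m + n))
        p = float(np.clip(special.kolmogorov(en * D), 0.0, 1.0))
    return TestResult("ks_two_sample", D, p, (m, n))


def pearson(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need equal-length samples with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one of the samples")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return TestResult("pearson", r, p, (n,))


def bh_fdr(pvals, q: float = 0.10) -> FdrResult:
    """Benjamini-Hochberg step-up adjusted p-values and rejections at rate q.

    adjusted_(i) = min_{j >= i} ( p_(j) · m / j ), capped at 1; rejection of
    hypothesis i iff adjusted_i <= q (equivalent to the step-up rule).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= q
    return FdrResult(raw=p, adjusted=adjusted, reject=reject, q=q)


# ---------------------------------------------------------------------------
# Lifespan-scaled age at death


def scaled_ages(
    records,
    life_history: pd.DataFrame,
    dictionary,
    lifespan_col: str = "max_longevity_months",
) -> pd.DataFrame:
    """Lifespan-scaled ages at death, flagged by tumour status.

    Returns a frame with columns ``clade, scientific_name, ratio, neoplasia``
    where ratio = age_at_death / species reference lifespan. Records without
    an age, without a resolved species, with an unmapped diagnosis term, or
    whose species lacks a lifespan entry are dropped.
    """
    lifespan = dict(
        zip(life_history["scientific_name"], life_history[lifespan_col])
    )
    rows = []
    for rec in records:
        if rec.age_at_death_months is None or rec.age_at_death_months <= 0:
            continue
        if not rec.scientific_name:
            continue
        ref = lifespan.get(rec.scientific_name)
        if ref is None or not np.isfinite(ref) or ref <= 0:
            continue
        try:
            cls = classify_record(rec, dictionary)
        except KeyError:
            continue
        rows.append(
            {
                "clade": rec.clade,
                "scientific_name": rec.scientific_name,
                "ratio": rec.age_at_death_months / float(ref),
                "neoplasia": cls in (CLASS_BENIGN, CLASS_MALIGNANT),
            }
        )
    return pd.DataFrame(rows, columns=["clade", "scientific_name", "ratio", "neoplasia"])


def scaled_age_comparison(
    records,
    life_history: pd.DataFrame,
    dictionary,
    lifespan_col: str = "max_longevity_months",
    min_per_arm: int = 2,
) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """Per-clade KS comparison of lifespan-scaled ages, tumour vs tumour-free.

    Returns the per-clade test results and a tidy density summary (Gaussian
    KDE evaluated on a ratio grid) for plotting. Clades with fewer than
    ``min_per_arm`` aged records in either arm are skipped with a log note.
    """
    df = scaled_ages(records, life_history, dictionary, lifespan_col)
    results: dict[str, TestResult] = {}
    dens_rows = []
    for clade, sub in df.groupby("clade"):
        neo = sub.loc[sub["neoplasia"], "ratio"].to_numpy()
        non = sub.loc[~sub["neoplasia"], "ratio"].to_numpy()
        if len(neo) < min_per_arm or len(non) < min_per_arm:
            logger.warning(
                "clade %s skipped: %d neoplasia / %d non-neoplasia aged records",
                clade,
                len(neo),
                len(non),
            )
            continue
        results[clade] = ks_two_sample(neo, non)
        grid = np.linspace(0.0, max(2.0, df["ratio"].max()), 101)
        for arm, values in (("neoplasia", neo), ("non_neoplasia", non)):
            if len(values) >= 3 and np.std(values) > 0:
                dens = sps.gaussian_kde(values)(grid)
            else:
                dens = np.full_like(grid, np.nan)
            dens_rows.extend(
                {"clade": clade, "arm": arm, "ratio": g, "density": d}
                for g, d in zip(grid, dens)
            )
    return results, pd.DataFrame(dens_rows, columns=["clade", "arm", "ratio", "density"])
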