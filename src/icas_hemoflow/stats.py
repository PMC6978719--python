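"""Nonparametric statistics for the lesion cohort analyses.

All test statistics are computed from their defining formulas (average
ranks for ties throughout); p-values default to the classical asymptotic
approximations and can instead be computed exactly (enumeration / dynamic
programming) or by seeded Monte-Carlo permutation, which matters at the
small block sizes typical of per-lesion repeated measurements.

Covariate adjustment ("adjusted by age and sex") is partial rank
correlation: all variables are rank-transformed, the x- and y-ranks are
residualised on the covariate ranks by least squares, and the residuals are
correlated; sex enters as a 0/1 indicator.  Two-sided p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (
    ConstantInputError,
    DegenerateAdjustmentError,
    InputError,
    StatisticsError,
    SubgroupSizeError,
)


@dataclass
class StatResult:
    """One test outcome: statistic, degrees of freedom, p, and context."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    adjusted_p: float | None = None
    r_s: float | None = None
    n: int | None = None
    extra: dict = field(default_factory=dict)


def _rank(x: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(x)):
        raise InputError("rank statistics require finite values "
                         "(drop undefined indices first)")
    return sps.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _t_p_value(r: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman_rank(x, y, p_method: str = "t", n_perm: int = 100_000,
                  seed: int = 0) -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    ``p_method``: "t" (t approximation, n-2 df), "exact" (full enumeration,
    n <= 8) or "permutation" (seeded Monte Carlo).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise InputError("need n >= 3")
    rx, ry = _rank(x), _rank(y)
    r_s = _pearson(rx, ry)

    if p_method == "t":
        p = _t_p_value(r_s, n - 2)
    elif p_method in ("exact", "permutation"):
        p = _permutation_p_corr(rx, ry, r_s, p_method, n_perm, seed)
    else:
        raise InputError(f"unknown p_method {p_method!r}")
    return StatResult(name="spearman", statistic=r_s, p_value=p, df=n - 2,
                      r_s=r_s, n=n)


def _permutation_p_corr(rx, ry, r_obs, method, n_perm, seed) -> float:
    """Two-sided permutation p for a rank correlation (|r| >= |r_obs|)."""
    n = len(rx)
    tol = 1e-12
    if method == "exact":
        if n > 8:
            raise InputError("exact enumeration limited to n <= 8")
        from itertools import permutations

        count = total = 0
        for perm in permutations(range(n)):
            r = _pearson(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(r_obs) - tol:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = _pearson(rx, ry[rng.permutation(n)])
        if abs(r) >= abs(r_obs) - tol:
            count += 1
    return (count + 1) / (n_perm + 1)


def partial_spearman(x, y, covariates, p_method: str = "t") -> StatResult:
    """Rank correlation of x and y adjusted for covariates.

    Rank-transforms every variable, residualises the x- and y-ranks on the
    covariate ranks (with intercept) by least squares, and correlates the
    residuals; p from the t approximation with n - 2 - k df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] == len(x) and Z.ndim == 2:
        pass
    elif Z.shape[1] == len(x):
        Z = Z.T
    else:
        raise InputError("covariates shape mismatch")
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise InputError("need n > number of covariates + 2")

    rx, ry = _rank(x), _rank(y)
    RZ = np.column_stack([np.ones(n)]
                         + [_rank(Z[:, j]) for j in range(k)])
    # drop covariate columns that are constant after ranking
    keep = [0] + [j for j in range(1, k + 1) if np.ptp(RZ[:, j]) > 0]
    RZ = RZ[:, keep]
    if np.linalg.matrix_rank(RZ) < RZ.shape[1]:
        raise DegenerateAdjustmentError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(RZ, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(RZ, ry, rcond=None)
    ex = rx - RZ @ beta_x
    ey = ry - RZ @ beta_y
    df = n - 2 - k
    # A variable fully explained by the covariates leaves a residual of
    # numerical noise only; its partial correlation is zero by convention.
    floor = 1e-18 * (np.sum((rx - rx.mean()) ** 2)
                     + np.sum((ry - ry.mean()) ** 2))
    if np.sum(ex ** 2) <= floor or np.sum(ey ** 2) <= floor:
        return StatResult(name="partial_spearman", statistic=0.0,
                          p_value=1.0, df=df, r_s=0.0, n=n)
    r_s = _pearson(ex, ey)
    if p_method == "t":
        p = _t_p_value(r_s, df)
    else:
        raise InputError("partial_spearman supports p_method='t' only")
    return StatResult(name="partial_spearman", statistic=r_s, p_value=p,
                      df=df, r_s=r_s, n=n)


def friedman_test(block_matrix, p_method: str = "chi2",
                  n_perm: int = 100_000, seed: int = 0) -> StatResult:
    """Friedman test for k repeated measurements on n blocks.

    Within-block average ranks; Q = [12n/(k(k+1))] sum_j (Rbar_j -
    (k+1)/2)^2 with the standard tie correction; p from chi-square with
    k - 1 df, or from a seeded within-block permutation null.
    """
    X = np.asarray(block_matrix, float)
    if X.ndim != 2:
        raise InputError("block_matrix must be 2-D (blocks x treatments)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise InputError("need at least 2 blocks and 2 treatments")
    if not np.isfinite(X).all():
        raise InputError("missing cells not allowed")

    def q_statistic(M):
        R = np.apply_along_axis(_rank, 1, M)
        rbar = R.mean(axis=0)
        q = 12.0 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2.0) ** 2).sum()
        # tie correction
        t_sum = 0.0
        for row in M:
            _, counts = np.unique(row, return_counts=True)
            t_sum += (counts ** 3 - counts).sum()
        c = 1.0 - t_sum / (n * k * (k * k - 1.0))
        if c <= 0:
            return 0.0, 0.0
        return q / c, c

    q, _ = q_statistic(X)
    df = k - 1
    if p_method == "chi2":
        p = float(sps.chi2.sf(q, df)) if q > 0 else 1.0
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        # Vectorised within-block permutations; the tie correction is
        # permutation-invariant (each block keeps its value multiset).
        ranks = sps.rankdata(X, axis=1)
        _, c = q_statistic(X)
        tiled = np.broadcast_to(ranks, (n_perm, n, k)).copy()
        tiled = rng.permuted(tiled, axis=2)
        rbar = tiled.mean(axis=1)
        q_all = 12.0 * n / (k * (k + 1)) * (
            (rbar - (k + 1) / 2.0) ** 2).sum(axis=1)
        if c > 0:
            q_all = q_all / c
        count = int(np.sum(q_all >= q - 1e-12))
        p = (count + 1) / (n_perm + 1)
    else:
        raise InputError(f"unknown p_method {p_method!r}")
    return StatResult(name="friedman", statistic=float(q), p_value=p, df=df,
                      n=n)


def bonferroni_adjust(p_values) -> list[float]:
    """Multiply each p by the number of comparisons, capped at 1."""
    p = list(p_values)
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise InputError("p-values must lie in [0, 1]")
    m = len(p)
    return [min(1.0, v * m) for v in p]


def wilcoxon_signed_rank(x, y=None, p_method: str = "auto") -> StatResult:
    """Wilcoxon signed-rank test for paired samples (or a single sample of
    differences).

    Zeros are dropped (Wilcoxon's convention); exact null by dynamic
    programming when there are no ties among |d| and n <= 25, otherwise the
    normal approximation with tie correction.
    """
    d = np.asarray(x, float) - (0.0 if y is None else np.asarray(y, float))
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return StatResult(name="wilcoxon", statistic=0.0, p_value=1.0, n=0,
                          extra={"method": "degenerate"})
    ranks = _rank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    use_exact = (p_method == "exact"
                 or (p_method == "auto" and not has_ties and n <= 25))
    if use_exact:
        if has_ties:
            raise InputError("exact null undefined with tied |differences|")
        # distribution of W+ over all 2^n sign assignments, by DP over the
        # integer ranks 1..n
        max_w = n * (n + 1) // 2
        dist = np.zeros(max_w + 1)
        dist[0] = 1.0
        for r in range(1, n + 1):
            dist[r:] = dist[r:] + dist[:-r]
        dist /= dist.sum()
        w_int = int(round(w_plus))
        p_low = dist[:w_int + 1].sum()
        p_high = dist[w_int:].sum()
        p = float(min(1.0, 2.0 * min(p_low, p_high)))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        t_sum = 0.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        t_sum = (counts ** 3 - counts).sum()
        var = n * (n + 1) * (2 * n + 1) / 24.0 - t_sum / 48.0
        if var <= 0:
            return StatResult(name="wilcoxon", statistic=w_plus, p_value=1.0,
                              n=n, extra={"method": "degenerate"})
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return StatResult(name="wilcoxon", statistic=w_plus, p_value=min(p, 1.0),
                      n=n, extra={"method": method})


def pairwise_posthoc(block_matrix, pairs=None, alpha: float = 0.05,
                     require_friedman: bool = False) -> list[StatResult]:
    """Pairwise Wilcoxon signed-rank tests with Bonferroni adjustment.

    ``pairs`` is a list of column-index pairs (default: all pairs).  With
    ``require_friedman`` the post-hoc is only run when the Friedman test is
    significant at ``alpha``.
    """
    X = np.asarray(block_matrix, float)
    n, k = X.shape
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if require_friedman:
        fr = friedman_test(X)
        if fr.p_value >= alpha:
            raise StatisticsError(
                f"Friedman test not significant (p = {fr.p_value:.3g}); "
                "post-hoc comparisons not justified")
    results = []
    for (i, j) in pairs:
        r = wilcoxon_signed_rank(X[:, i], X[:, j])
        r.name = f"wilcoxon[{i}-{j}]"
        results.append(r)
    adj = bonferroni_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = a
    return results


def chi_square_independence(table) -> StatResult:
    """Pearson chi-square test of independence on an r x c count table."""
    T = np.asarray(table, float)
    if T.ndim != 2 or (T < 0).any():
        raise InputError("table must be a non-negative 2-D count array")
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise InputError("zero row/column margin")
    E = np.outer(row, col) / T.sum()
    chi2 = float(((T - E) ** 2 / E).sum())
    df = (T.shape[0] - 1) * (T.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return StatResult(name="chi_square", statistic=chi2, p_value=p, df=df,
                      n=int(T.sum()))


def cohen_kappa(agreement_table) -> StatResult:
    """Cohen's kappa from a square inter-rater agreement count table."""
    T = np.asarray(agreement_table, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1] or (T < 0).any():
        raise InputError("agreement table must be square and non-negative")
    total = T.sum()
    if total <= 0:
        raise InputError("empty agreement table")
    p_o = np.trace(T) / total
    p_e = float((T.sum(axis=1) * T.sum(axis=0)).sum() / total ** 2)
    if p_e >= 1.0:
        raise StatisticsError("kappa undefined: chance agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return StatResult(name="cohen_kappa", statistic=float(kappa),
                      p_value=float("nan"), n=int(total),
                      extra={"p_observed": float(p_o), "p_expected": p_e})


def threshold_split_correlation(stenosis, index, covariates,
                                cutoff: float = 50.0,
                                min_subgroup: int = 5
                                ) -> tuple[StatResult, StatResult]:
    """Covariate-adjusted rank correlation in the below-/at-or-above-cutoff
    stenosis subgroups (default split at 50% stenosis)."""
    stenosis = np.asarray(stenosis, float)
    index = np.asarray(index, float)
    Z = np.asarray(covariates, float)
    below = stenosis < cutoff
    above = ~below
    if below.sum() < min_subgroup or above.sum() < min_subgroup:
        raise SubgroupSizeError(
            f"subgroup too small: {int(below.sum())} below / "
            f"{int(above.sum())} at-or-above the {cutoff}% cutoff")
    res = []
    for mask, tag in ((below, "<cutoff"), (above, ">=cutoff")):
        r = partial_spearman(stenosis[mask], index[mask], Z[mask])
        r.name = f"split_spearman[{tag}]"
        r.extra["cutoff"] = cutoff
        res.append(r)
    return res[0], res[1]
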