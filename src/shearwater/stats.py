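"""Colony-comparison statistics: rank tests, 2x2 chi-square, transforms,
and a REML random-intercept mixed model.

The rank-sum statistic follows the convention W = (sum of ranks of the
first sample in the pooled ranking, average ranks for ties) minus
n1(n1+1)/2, i.e. the Mann-Whitney U of the first sample - the value R's
``wilcox.test`` prints.  P-values are exact by enumeration when there
are no ties and the enumeration is affordable, otherwise a normal
approximation with tie and continuity corrections is used (again the
convention of the usual statistical environments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "LmeResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "chi2_2x2",
    "arcsine_sqrt",
    "log_tx",
    "lme_random_intercept",
]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    W: float
    p: float
    method: str  # "exact" or "normal-with-ties"
    n1: int
    n2: int


def _exact_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts[u] = #arrangements with U = u.

    Classic subset-sum dynamic programme over the pooled ranks 1..N;
    counts of subsets of size n1 by rank sum, shifted to U.
    """
    N = n1 + n2
    smax = n1 * N
    ways = np.zeros((n1 + 1, smax + 1), dtype=float)
    ways[0, 0] = 1.0
    for v in range(1, N + 1):
        ways[1:, v:] += ways[:-1, :-v or None].copy()
    sums = ways[n1]  # counts of rank sums
    lo = n1 * (n1 + 1) // 2
    return sums[lo:lo + n1 * n2 + 1]


def wilcoxon_rank_sum(x, y) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test, first-sample W.

    Exact p by enumeration when the pooled sample has no ties and
    C(n1+n2, n1) <= 1e6; otherwise a normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    W = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and math.comb(n1 + n2, n1) <= 1_000_000:
        counts = _exact_counts(n1, n2)
        total = counts.sum()
        w = int(round(W))
        mu = n1 * n2 / 2.0
        if W > mu:
            p = 2.0 * counts[w:].sum() / total
        else:
            p = 2.0 * counts[:w + 1].sum() / total
        return RankTestResult(W=W, p=min(1.0, float(p)), method="exact", n1=n1, n2=n2)
    N = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
    diff = W - mu
    if sigma2 == 0:  # every pooled value identical
        p = 1.0
    else:
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2)
        p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(W=W, p=min(1.0, float(p)), method="normal-with-ties",
                          n1=n1, n2=n2)


def kruskal_wallis(*samples) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p (k-1 df).

    Thin generalisation of the rank machinery for >2 groups.
    """
    samples = [np.asarray(s, float) for s in samples]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least two non-empty samples")
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    H = 0.0
    i = 0
    for s in samples:
        r = ranks[i:i + len(s)]
        H += r.sum() ** 2 / len(s)
        i += len(s)
    H = 12.0 / (N * (N + 1.0)) * H - 3.0 * (N + 1.0)
    _, t = np.unique(pooled, return_counts=True)
    corr = 1.0 - np.sum(t**3 - t) / (N**3 - N)
    if corr > 0:
        H /= corr
    p = float(sps.chi2.sf(H, df=len(samples) - 1))
    return float(H), p


# ---------------------------------------------------------------------------
# 2x2 chi-square and transforms
# ---------------------------------------------------------------------------

def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = True):
    """Pearson chi-square on a 2x2 table, 1 df.

    ``correction`` applies the Yates continuity correction (the default
    of the usual statistical environments).  Counts are the table rows
    (a, b) and (c, d); any zero margin is an error.
    """
    tab = np.array([[a, b], [c, d]], float)
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    n = tab.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(row, col) / n
    diff = np.abs(tab - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(sps.chi2.sf(stat, df=1))


def arcsine_sqrt(p):
    """Variance-stabilising arcsine-square-root transform of a proportion."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return out if out.ndim else float(out)


def log_tx(x):
    """Natural log of a positive quantity."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("log transform requires positive values")
    out = np.log(x)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (REML)
# ---------------------------------------------------------------------------

@dataclass
class LmeResult:
    """REML fit of y = Xb + u_group + e with a scalar random intercept."""

    beta: dict
    se: dict
    sigma_u2: float
    sigma_e2: float
    f_stat: float
    df_num: int
    df_den: int
    p: float
    converged: bool
    objective_trace: list = field(repr=False, default_factory=list)
    method: str = "REML"


def _reml_profile(loglam, X, y, groups_idx, group_sizes):
    """-2 restricted log-likelihood (profiled) at log variance ratio.

    lambda = sigma_u^2 / sigma_e^2.  Block structure V_g = I + lambda J
    gives closed-form inverses per group (Woodbury), so the profile is
    O(n) per evaluation.
    """
    lam = math.exp(loglam)
    n, p = X.shape
    # V^-1 x = x - (lam / (1 + m lam)) * J x  per group
    shr = lam / (1.0 + group_sizes * lam)          # per group
    Xg_sum = np.zeros((len(group_sizes), p))
    yg_sum = np.zeros(len(group_sizes))
    np.add.at(Xg_sum, groups_idx, X)
    np.add.at(yg_sum, groups_idx, y)
    XtVX = X.T @ X - (Xg_sum * shr[:, None]).T @ Xg_sum
    XtVy = X.T @ y - Xg_sum.T @ (shr * yg_sum)
    ytVy = y @ y - yg_sum @ (shr * yg_sum)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy
    rss = max(rss, 1e-300)
    sigma_e2 = rss / (n - p)
    logdetV = float(np.sum(np.log1p(group_sizes * lam)))
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    crit = (n - p) * math.log(sigma_e2) + logdetV + logdetXtVX
    return crit, beta, sigma_e2, XtVX


def lme_random_intercept(response, covariate, group_ids, site=None,
                         lam_bounds=(-15.0, 15.0)):
    """Random-intercept LME fit by direct REML profile optimisation.

    Model: ``y = b0 + b1*covariate (+ site) + u_group + e`` with
    ``u_group ~ N(0, sigma_u^2)`` and ``e ~ N(0, sigma_e^2)``.  The
    variance ratio is profiled on a coarse grid and refined by
    golden-section search; ``objective_trace`` records the running best
    -2 restricted log-likelihood (non-increasing by construction).  A
    boundary solution is reported as a singular fit with
    ``sigma_u2 = 0``, not an error.  The marginal F test for the
    covariate uses the nested (containment) denominator df: for a
    covariate varying within groups, ``n - #groups - #slopes``; for a
    group-level covariate, ``#groups - 1 - #group-level slopes``.
    """
    y = np.asarray(response, float)
    x = np.asarray(covariate, float)
    groups = np.asarray(group_ids)
    n = len(y)
    if len(x) != n or len(groups) != n:
        raise ValueError("response, covariate and group_ids must align")
    uniq, groups_idx = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if n < 3:
        raise ValueError("need at least 3 observations")
    cols = [np.ones(n), x]
    names = ["intercept", "covariate"]
    if site is not None:
        site = np.asarray(site)
        levels = np.unique(site)
        for lev in levels[1:]:  # treatment coding, first level reference
            cols.append((site == lev).astype(float))
            names.append(f"site[{lev}]")
    X = np.column_stack(cols)
    p = X.shape[1]
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")
    group_sizes = np.bincount(groups_idx).astype(float)

    def obj(ll):
        return _reml_profile(ll, X, y, groups_idx, group_sizes)[0]

    grid = np.linspace(lam_bounds[0], lam_bounds[1], 61)
    vals = [obj(g) for g in grid]
    trace = list(np.minimum.accumulate(vals))
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    # golden-section refinement, recording the running best
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = obj(c), obj(d)
    best = min(trace[-1], fc, fd)
    trace.append(best)
    for _ in range(60):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = obj(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = obj(d)
        best = min(best, fc, fd)
        trace.append(best)
        if b - a < 1e-10:
            break
    ll_hat = (a + b) / 2.0
    crit, beta, sigma_e2, XtVX = _reml_profile(ll_hat, X, y, groups_idx, group_sizes)
    if not np.isfinite(crit):
        raise RuntimeError(f"REML optimisation failed to converge (criterion {crit})")
    lam = math.exp(ll_hat)
    if ll_hat <= lam_bounds[0] + 1e-6:
        lam = 0.0  # singular fit at the boundary
    sigma_u2 = lam * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    n_groups = len(uniq)
    n_slopes = p - 1
    varies_within = any(
        len(np.unique(x[groups_idx == gidx])) > 1 for gidx in range(n_groups))
    if varies_within:
        df_den = n - n_groups - n_slopes
    else:
        df_den = n_groups - 1 - n_slopes
    if df_den <= 0:
        raise ValueError("no denominator degrees of freedom for the F test")
    f_stat = float((beta[1] / se[1]) ** 2)
    pval = float(sps.f.sf(f_stat, 1, df_den))
    return LmeResult(
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        f_stat=f_stat,
        df_num=1,
        df_den=int(df_den),
        p=pval,
        converged=True,
        objective_trace=trace,
    )
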