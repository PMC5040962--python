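"""Heteroscedasticity-aware statistical procedures used by the analysis.

Welch one-way ANOVA, Games-Howell pairwise comparisons, Cohen's d,
Brown-Forsythe (median-centred) Levene test, Spearman and partial Spearman
rank correlation, Mood's median test, Wilcoxon signed-rank median
confidence intervals, least-squares trend lines, and empirical variograms.

All formulas are implemented directly (scipy supplies only reference
distributions), so each can be cross-checked against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist

__all__ = ["StatResult", "welch_anova", "games_howell", "cohens_d", "levene",
           "spearman", "partial_spearman", "moods_median",
           "wilcoxon_median_ci", "signed_rank_cdf", "linear_trend",
           "empirical_variogram"]


@dataclass
class StatResult:
    name: str
    statistic: float
    p: float
    df: tuple | float | None = None
    effect_size: float | None = None
    ci: tuple | None = None          # (level, lo, hi)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0 <= self.p <= 1):
            raise ValueError("p outside [0, 1]")
        if self.ci is not None and self.ci[1] > self.ci[2]:
            raise ValueError("CI lower bound exceeds upper bound")


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        groups = list(groups.values())
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    return gs


def welch_anova(groups) -> StatResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    F* = [sum w_i (m_i - m_w)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) * L]
    with w_i = n_i / s_i^2, L = sum (1 - w_i/W)^2 / (n_i - 1) and
    denominator df (k^2 - 1) / (3 L).
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.all(v == 0):
        if np.all(m == m[0]):
            return StatResult("welch_anova", 0.0, 1.0, df=(k - 1, np.inf))
        raise ValueError("zero within-group variance in every group")
    if np.any(v == 0):
        raise ValueError("zero within-group variance")
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    lam = (((1 - w / W) ** 2) / (n - 1)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1 + 2 * (k - 2) / (k ** 2 - 1) * lam
    F = num / den
    df2 = (k ** 2 - 1) / (3 * lam)
    p = float(sps.f.sf(F, k - 1, df2))
    return StatResult("welch_anova", float(F), p, df=(k - 1, float(df2)))


def games_howell(groups, labels=None, conf: float = 0.95) -> list[StatResult]:
    """Games-Howell pairwise comparisons on unpooled variances.

    For each pair: t on Welch standard error, Welch-Satterthwaite df, and
    p from the studentized-range distribution with q = |t| * sqrt(2) over
    all k groups; the CI uses the same critical q.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        groups = list(groups.values())
    gs = _as_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            if se2 == 0:
                raise ValueError("zero variance in both groups of a pair")
            se = np.sqrt(se2)
            t = (m[i] - m[j]) / se
            df = se2 ** 2 / ((v[i] / n[i]) ** 2 / (n[i] - 1)
                             + (v[j] / n[j]) ** 2 / (n[j] - 1))
            p = float(np.clip(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, df), 0, 1))
            qcrit = sps.studentized_range.ppf(conf, k, df)
            half = qcrit / np.sqrt(2) * se
            out.append(StatResult(
                f"games_howell[{labels[i]}-{labels[j]}]",
                float(t), p, df=float(df),
                effect_size=float(m[i] - m[j]),
                ci=(conf, float(m[i] - m[j] - half), float(m[i] - m[j] + half)),
                extra={"group1": labels[i], "group2": labels[j]},
            ))
    return out


def cohens_d(g1, g2) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation.

    Positive when mean(g1) > mean(g2).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((g1.mean() - g2.mean()) / np.sqrt(sp2))


def levene(groups, center: str = "median") -> StatResult:
    """Levene's test for equality of variances; the default median
    centring is the Brown-Forsythe variant."""
    gs = _as_groups(groups)
    cfun = {"median": np.median, "mean": np.mean}[center]
    z = [np.abs(g - cfun(g)) for g in gs]
    k = len(z)
    n = np.array([len(g) for g in z], dtype=float)
    N = n.sum()
    zbar = np.concatenate(z).mean()
    zm = np.array([g.mean() for g in z])
    num = (n * (zm - zbar) ** 2).sum() / (k - 1)
    den = sum(((g - g.mean()) ** 2).sum() for g in z) / (N - k)
    if den == 0:
        return StatResult("levene", 0.0, 1.0, df=(k - 1, float(N - k)))
    W = num / den
    return StatResult("levene", float(W), float(sps.f.sf(W, k - 1, N - k)),
                      df=(k - 1, float(N - k)))


# ---------------------------------------------------------------------------
# rank correlation

def _rank(x):
    return sps.rankdata(np.asarray(x, dtype=float))  # average ties


def _t_pvalue(r: float, df: int) -> float:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), df))


def spearman(x, y) -> StatResult:
    """Spearman's r_s: Pearson correlation of average-tie ranks, p from the
    t approximation with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r = float(np.corrcoef(_rank(x), _rank(y))[0, 1])
    return StatResult("spearman", r, _t_pvalue(r, n - 2), df=n - 2)


def partial_spearman(x, y, controls=None) -> StatResult:
    """Partial Spearman correlation of x and y given control variables.

    Computed as the Pearson correlation of the residuals of rank(x) and
    rank(y) after least-squares regression on the control ranks — the
    residual form of the rank-correlation-matrix inversion, identical to
    it whenever that matrix is nonsingular and well defined when a control
    duplicates x or y (a zero-variance residual gives r = 0). With no
    controls this is exactly the simple Spearman coefficient. p from the
    t approximation with df = n - 2 - #controls.
    """
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        res = spearman(x, y)
        return StatResult("partial_spearman", res.statistic, res.p, df=res.df)
    ctrl = np.atleast_2d(np.asarray(controls, dtype=float))
    n = len(np.asarray(x))
    if ctrl.shape[0] == n and ctrl.shape[1] != n:
        ctrl = ctrl.T  # accept (n, k) or (k, n)
    k = ctrl.shape[0]
    data = np.vstack([np.asarray(x, dtype=float), np.asarray(y, dtype=float), ctrl])
    if any(np.ptp(row) == 0 for row in data):
        raise ValueError("constant input vector")
    df = n - 2 - k
    if df < 1:
        raise ValueError("too few observations for the number of controls")
    ranks = np.vstack([_rank(row) for row in data])
    design = np.vstack([ranks[2:], np.ones(n)]).T
    coef, *_ = np.linalg.lstsq(design, ranks[:2].T, rcond=None)
    resid = ranks[:2].T - design @ coef
    sx = float(resid[:, 0] @ resid[:, 0])
    sy = float(resid[:, 1] @ resid[:, 1])
    if sx <= 1e-12 * n or sy <= 1e-12 * n:
        # a control explains x or y exactly: nothing left to correlate
        return StatResult("partial_spearman", 0.0, 1.0, df=df)
    r = float(resid[:, 0] @ resid[:, 1] / np.sqrt(sx * sy))
    return StatResult("partial_spearman", r, _t_pvalue(r, df), df=df)


# ---------------------------------------------------------------------------
# medians

def moods_median(g1, g2) -> StatResult:
    """Mood's median test: chi-square (no continuity correction) on the
    2x2 table of counts above vs at-or-below the grand median."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    combined = np.concatenate([g1, g2])
    if len(combined) < 4:
        raise ValueError("need combined n >= 4")
    if np.ptp(combined) == 0:
        raise ValueError("all values equal; median table degenerate")
    gm = np.median(combined)
    table = np.array([[np.sum(g1 > gm), np.sum(g2 > gm)],
                      [np.sum(g1 <= gm), np.sum(g2 <= gm)]], dtype=float)
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate median table")
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(((table - exp) ** 2 / exp).sum())
    return StatResult("moods_median", chi2, float(sps.chi2.sf(chi2, 1)), df=1,
                      extra={"table": table, "grand_median": float(gm)})


def signed_rank_cdf(n: int) -> np.ndarray:
    """Exact null CDF of the Wilcoxon signed-rank statistic T+ for sample
    size n (no ties/zeros), by subset-sum enumeration."""
    M = n * (n + 1) // 2
    counts = np.zeros(M + 1)
    counts[0] = 1
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return np.cumsum(counts / 2.0 ** n)


def wilcoxon_median_ci(sample, nominal: float = 0.95,
                       method: str = "approx") -> tuple[float, float, float, float]:
    """Median (Hodges-Lehmann) estimate and signed-rank confidence interval
    on the ordered Walsh averages.

    ``method='approx'`` (default) follows the procedure of common
    statistical packages: the critical value is
    d = floor(mu + z_{alpha/2} sigma) from the normal approximation of the
    signed-rank null (mu = n(n+1)/4, sigma^2 = n(n+1)(2n+1)/24), the
    interval is (W_(d+1), W_(M-d)), and the achieved confidence level is
    the continuity-corrected normal estimate 1 - 2 Phi((d + 0.5 - mu)/sigma).
    This reproduces published achieved levels (94.8% at n = 21, 94.5% at
    n = 12, 95.6% at n = 9), which exact enumeration does not.

    ``method='exact'`` instead picks the interval whose exactly enumerated
    coverage 1 - 2 P(T <= d) is nearest the nominal level (ties toward the
    lower level) and reports that exact coverage.

    Returns ``(median, lo, hi, achieved_level)`` with the level as a
    fraction; the median is the Hodges-Lehmann estimate (median of the
    Walsh averages).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    M = n * (n + 1) // 2
    i, j = np.triu_indices(n)
    walsh = np.sort((x[i] + x[j]) / 2.0)
    assert len(walsh) == M

    mu = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    if method == "approx":
        d = int(np.floor(mu + sps.norm.ppf((1 - nominal) / 2) * sd))
        if d < 0:
            raise ValueError("sample too small for a two-sided interval at "
                             f"nominal level {nominal}")
        level = float(1 - 2 * sps.norm.cdf((d + 0.5 - mu) / sd))
    elif method == "exact":
        cdf = signed_rank_cdf(n)
        ds = np.arange(0, M // 2)
        cov = 1 - 2 * cdf[ds]
        ok = cov > 0
        if not ok.any():
            raise ValueError("sample too small for a two-sided interval")
        ds, cov = ds[ok], cov[ok]
        # nearest achievable level; on a tie prefer the lower level (larger d)
        order = np.lexsort((-ds, np.abs(cov - nominal)))
        d = int(ds[order[0]])
        level = float(cov[order[0]])
    else:
        raise ValueError("method must be 'approx' or 'exact'")
    lo = float(walsh[d])           # W_(d+1), 1-based
    hi = float(walsh[M - d - 1])   # W_(M-d)
    return float(np.median(walsh)), lo, hi, level


# ---------------------------------------------------------------------------
# trends and variograms

def linear_trend(x, y) -> tuple[float, float]:
    """Ordinary least-squares line; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def empirical_variogram(values, coords, lag_bins):
    """Empirical semivariogram gamma(h) = mean squared difference / 2 per
    lag bin.

    Returns ``(lag_centres, gamma, pair_counts)``; bins with no pairs give
    NaN semivariance.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) != len(values):
        raise ValueError("coords must be (n, d) matching values")
    if len(values) < 2 or np.ptp(coords, axis=0).max() == 0:
        raise ValueError("degenerate coordinates")
    lag_bins = np.asarray(lag_bins, dtype=float)
    d = pdist(coords)
    sq = pdist(values[:, None], metric="sqeuclidean")
    idx = np.digitize(d, lag_bins) - 1
    nb = len(lag_bins) - 1
    gamma = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b] > 0:
            gamma[b] = 0.5 * sq[sel].mean()
    centres = 0.5 * (lag_bins[:-1] + lag_bins[1:])
    return centres, gamma, counts
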