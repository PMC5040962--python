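import numpy as np
import pytest
from scipy import stats as sps

from abysshill import stats as st


# ---------------------------------------------------------------------------
# Welch ANOVA

def test_welch_identical_groups():
    res = st.welch_anova([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_welch_two_groups_equals_classic(rng):
    # with k = 2 and equal n / equal sample variances the correction term
    # vanishes and Welch F equals the classic one-way F
    a = rng.normal(size=15)
    b = (rng.normal(size=15) - 0) * (a.std(ddof=1) / 1.0)
    b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + a.mean() + 0.7
    res = st.welch_anova([a, b])
    classic = sps.f_oneway(a, b)
    assert res.statistic == pytest.approx(classic.statistic, rel=1e-10)
    assert res.p == pytest.approx(classic.pvalue, rel=1e-8)


def test_welch_matches_pingouin_oracle(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    groups = [rng.normal(0, 1, 5), rng.normal(0.5, 2, 7), rng.normal(1, 3, 9)]
    res = st.welch_anova(groups)
    df = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat(["a", "b", "c"], [5, 7, 9]),
    })
    oracle = pg.welch_anova(data=df, dv="y", between="g")
    assert res.statistic == pytest.approx(float(oracle["F"].iloc[0]), abs=1e-10)
    assert res.df[1] == pytest.approx(float(oracle["ddof2"].iloc[0]), abs=1e-10)
    assert res.p == pytest.approx(float(oracle["p_unc"].iloc[0]), abs=1e-12)


def test_welch_formula_oracle(rng):
    # direct evaluation of Welch's published formulas, written independently
    groups = [rng.normal(0, 1, 5), rng.normal(0.2, 1.5, 7), rng.normal(0.9, 0.5, 9)]
    k = len(groups)
    n = np.array([len(g) for g in groups])
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    A = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    F = A / (1 + 2 * (k - 2) / (k ** 2 - 1) * lam)
    df2 = (k ** 2 - 1) / (3 * lam)
    res = st.welch_anova(groups)
    assert res.statistic == pytest.approx(F, abs=1e-10)
    assert res.df[1] == pytest.approx(df2, abs=1e-10)


def test_welch_requires_two_groups():
    with pytest.raises(ValueError):
        st.welch_anova([[1.0, 2.0]])
    with pytest.raises(ValueError):
        st.welch_anova([[1.0], [2.0]])


def test_welch_type_one_error_heteroscedastic():
    """Type-I error under H0 with sd ratio 4 and unbalanced n stays near
    0.05 — the property motivating the choice of Welch's test."""
    rng = np.random.default_rng(2024)
    n_rep = 2000
    rejections = 0
    for _ in range(n_rep):
        groups = [rng.normal(0, 1, 20), rng.normal(0, 2, 40),
                  rng.normal(0, 4, 80)]
        if st.welch_anova(groups).p < 0.05:
            rejections += 1
    assert rejections / n_rep == pytest.approx(0.05, abs=0.015)


# ---------------------------------------------------------------------------
# Games-Howell

def test_gh_identical_groups():
    rng = np.random.default_rng(5)
    g = rng.normal(size=30)
    res = st.games_howell([g, g.copy()])
    assert len(res) == 1
    assert res[0].p > 0.99
    assert res[0].ci[1] < 0 < res[0].ci[2]


def test_gh_two_groups_equals_welch_t(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(1, 3, 20)
    res = st.games_howell([a, b])[0]
    t, p = sps.ttest_ind(a, b, equal_var=False)
    # for k = 2, q = sqrt(2)|t| maps the studentized range onto the
    # two-sided Welch-t probability
    assert abs(res.statistic) == pytest.approx(abs(t), rel=1e-12)
    assert res.p == pytest.approx(p, abs=1e-5)


def test_gh_matches_pingouin_oracle(rng):
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0.8, 2, 14),
              "c": rng.normal(1.5, 0.5, 8)}
    res = {(r.extra["group1"], r.extra["group2"]): r
           for r in st.games_howell(groups)}
    df = pd.DataFrame({
        "y": np.concatenate(list(groups.values())),
        "g": np.repeat(list(groups), [len(v) for v in groups.values()]),
    })
    oracle = pg.pairwise_gameshowell(data=df, dv="y", between="g")
    for row in oracle.itertuples():
        r = res[(row.A, row.B)]
        assert r.effect_size == pytest.approx(row.diff, rel=1e-9)
        assert abs(r.statistic) == pytest.approx(abs(row.T), rel=1e-9)
        assert r.df == pytest.approx(row.df, rel=1e-9)
        assert r.p == pytest.approx(row.pval, abs=1e-6)


def test_gh_relabelling_symmetry(rng):
    a = rng.normal(0, 1, 10)
    b = rng.normal(0.5, 2, 15)
    c = rng.normal(1, 1, 12)
    p1 = sorted(r.p for r in st.games_howell([a, b, c]))
    p2 = sorted(r.p for r in st.games_howell([c, a, b]))
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_gh_family_at_least_welch_t(rng):
    # each Games-Howell p >= the corresponding unadjusted Welch-t p
    for _ in range(20):
        groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3),
                             rng.integers(5, 30)) for _ in range(4)]
        for r in st.games_howell(groups):
            i = int(r.extra["group1"][1:])
            j = int(r.extra["group2"][1:])
            _, p_welch = sps.ttest_ind(groups[i], groups[j], equal_var=False)
            assert r.p >= p_welch - 1e-9


# ---------------------------------------------------------------------------
# effect size, Levene

def test_cohens_d_zero():
    assert st.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0


def test_cohens_d_unit(rng):
    g1 = rng.normal(size=50)
    g2 = g1 + np.sqrt(((len(g1) - 1) * g1.var(ddof=1) * 2)
                      / (2 * len(g1) - 2))  # shift by exactly one pooled SD
    assert st.cohens_d(g2, g1) == pytest.approx(1.0, rel=1e-12)


def test_cohens_d_errors():
    with pytest.raises(ValueError):
        st.cohens_d([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        st.cohens_d([1.0, 1.0], [2.0, 2.0])


def test_levene_identical_groups():
    res = st.levene([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_levene_matches_scipy(rng):
    groups = [rng.normal(0, 1, 20), rng.normal(0, 3, 25), rng.normal(2, 1, 15)]
    res = st.levene(groups)
    W, p = sps.levene(*groups, center="median")
    assert res.statistic == pytest.approx(W, rel=1e-12)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_levene_type_one_error():
    rng = np.random.default_rng(99)
    rej = sum(st.levene([rng.normal(0, 1, 30), rng.normal(0, 1, 30)]).p < 0.05
              for _ in range(500))
    assert rej / 500 == pytest.approx(0.05, abs=0.02)


def test_levene_power():
    rng = np.random.default_rng(7)
    res = st.levene([rng.normal(0, 1, 100), rng.normal(0, 3, 100)])
    assert res.p < 0.01


# ---------------------------------------------------------------------------
# rank correlation

def test_spearman_perfect():
    x = np.arange(10.0)
    res = st.spearman(x, x ** 3)  # monotone
    assert res.statistic == pytest.approx(1.0)


def test_spearman_matches_scipy(rng):
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    res = st.spearman(x, y)
    r, p = sps.spearmanr(x, y)
    assert res.statistic == pytest.approx(r, rel=1e-12)
    assert res.p == pytest.approx(p, rel=1e-9)


def test_spearman_constant_rejected():
    with pytest.raises(ValueError):
        st.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_spearman_monotone_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r1 = st.spearman(x, y).statistic
    r2 = st.spearman(np.exp(x), y ** 3).statistic if np.all(y != 0) else None
    assert r1 == pytest.approx(st.spearman(np.exp(x), np.exp(y)).statistic)


def test_partial_empty_controls_is_simple(rng):
    x = rng.normal(size=25)
    y = x + rng.normal(size=25)
    simple = st.spearman(x, y)
    for controls in (None, [], np.empty((0, 25))):
        part = st.partial_spearman(x, y, controls)
        assert part.statistic == pytest.approx(simple.statistic, abs=1e-15)
        assert part.p == pytest.approx(simple.p, abs=1e-15)


def test_partial_spearman_duplicate_control_collapses(rng):
    # y = x + noise, z = x: controlling z leaves nothing of x to correlate
    n = 60
    x = rng.normal(size=n)
    z = x.copy()
    y = x + 0.3 * rng.normal(size=n)
    res = st.partial_spearman(x, y, [z])
    simple = st.spearman(x, y)
    assert abs(res.statistic) < 1e-6 < abs(simple.statistic)
    assert res.p == 1.0


def test_partial_spearman_matrix_inversion_oracle(rng):
    # well-conditioned triple: residual form equals the inversion of the
    # rank correlation matrix (independent oracle) to high precision
    n = 80
    z = rng.normal(size=n)
    x = 0.8 * z + rng.normal(size=n)
    y = 0.5 * z + 0.4 * x + rng.normal(size=n)
    res = st.partial_spearman(x, y, [z])
    ranks = np.vstack([sps.rankdata(v) for v in (x, y, z)])
    P = np.linalg.inv(np.corrcoef(ranks))
    oracle = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    assert res.statistic == pytest.approx(oracle, abs=1e-8)
    assert abs(res.statistic) < abs(st.spearman(x, y).statistic)


def test_partial_spearman_control_shapes(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    z = rng.normal(size=(2, 30))
    r1 = st.partial_spearman(x, y, z)
    r2 = st.partial_spearman(x, y, z.T)  # (n, k) accepted too
    assert r1.statistic == pytest.approx(r2.statistic)


# ---------------------------------------------------------------------------
# medians

def test_moods_identical():
    g = [1.0, 2.0, 3.0, 4.0]
    res = st.moods_median(g, list(g))
    assert res.statistic == 0.0


def test_moods_hand_computed():
    # 2x2 table (9,1 / 1,9): chi2 = 20*(81-1)^2/10^4 = 12.8
    g1 = [2.0] * 9 + [1.0]
    g2 = [1.0] * 9 + [2.0]
    res = st.moods_median(g1, g2)
    assert res.statistic == pytest.approx(12.8)
    assert res.p < 0.001


def test_moods_monotone_invariance(rng):
    g1 = rng.normal(size=15)
    g2 = rng.normal(1, 1, size=20)
    r1 = st.moods_median(g1, g2)
    r2 = st.moods_median(np.exp(g1), np.exp(g2))
    assert r1.statistic == pytest.approx(r2.statistic)


def test_moods_degenerate():
    with pytest.raises(ValueError):
        st.moods_median([1.0, 1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank median CI

@pytest.mark.parametrize("n,want", [(21, 94.8), (12, 94.5), (9, 95.6)])
def test_wilcoxon_ci_published_levels(n, want, rng):
    *_, level = st.wilcoxon_median_ci(rng.normal(size=n))
    assert round(100 * level, 1) == want


def test_wilcoxon_ci_exact_levels(rng):
    # exact enumeration gives the nearest achievable exact level instead
    *_, level = st.wilcoxon_median_ci(rng.normal(size=21), method="exact")
    assert round(100 * level, 1) == 95.0


def test_wilcoxon_ci_endpoints_are_walsh_averages(rng):
    x = rng.normal(size=12)
    med, lo, hi, _ = st.wilcoxon_median_ci(x)
    i, j = np.triu_indices(len(x))
    walsh = np.sort((np.sort(x)[i] + np.sort(x)[j]) / 2)
    assert lo in walsh and hi in walsh
    assert lo <= med <= hi
    assert med == pytest.approx(np.median(walsh))


def test_wilcoxon_ci_too_small():
    with pytest.raises(ValueError):
        st.wilcoxon_median_ci([1.0, 2.0, 3.0])


def test_signed_rank_cdf_small_n():
    # n=3: T+ in {0..6}, pmf = (1,1,1,2,1,1,1)/8
    cdf = st.signed_rank_cdf(3)
    np.testing.assert_allclose(cdf, np.cumsum([1, 1, 1, 2, 1, 1, 1]) / 8)


# ---------------------------------------------------------------------------
# trend, variogram

def test_linear_trend_exact():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    slope, intercept = st.linear_trend(x, 2.5 * x - 1.0)
    assert slope == pytest.approx(2.5)
    assert intercept == pytest.approx(-1.0)


def test_linear_trend_zero_slope():
    slope, _ = st.linear_trend([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
    assert slope == pytest.approx(0.0)


def test_linear_trend_matches_normal_equations(rng):
    x = rng.normal(size=50)
    y = 1.5 * x + rng.normal(size=50)
    slope, intercept = st.linear_trend(x, y)
    o_slope, o_intercept = np.polyfit(x, y, 1)
    assert slope == pytest.approx(o_slope, rel=1e-10)
    assert intercept == pytest.approx(o_intercept, rel=1e-10)


def test_variogram_constant_field(rng):
    coords = rng.uniform(0, 100, size=(50, 2))
    _, gamma, counts = st.empirical_variogram(np.full(50, 3.0), coords,
                                              np.linspace(0, 150, 8))
    assert np.nanmax(gamma) == pytest.approx(0.0)


def test_variogram_white_noise_flat(rng):
    # pairs share points, so per-bin scatter exceeds the naive
    # independent-pairs standard error; 15% of the sill is a safe envelope
    n = 400
    coords = rng.uniform(0, 100, size=(n, 2))
    vals = rng.normal(size=n)
    _, gamma, counts = st.empirical_variogram(vals, coords,
                                              np.linspace(0, 100, 9))
    var = vals.var()
    used = counts > 200
    assert np.all(np.abs(gamma[used] - var) < 0.15 * var)


def test_variogram_range_recovery():
    """Parameter recovery: exponential-covariance field, fitted range
    within 25% of truth."""
    from scipy.optimize import curve_fit

    rng = np.random.default_rng(11)
    n = 2000
    r0 = 15.0
    coords = rng.uniform(0, 300, size=(n, 2))  # domain >> range
    d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                 coords[:, None, 1] - coords[None, :, 1])
    cov = np.exp(-d / r0)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    vals = L @ rng.normal(size=n)
    lags = np.linspace(0, 50, 11)
    centres, gamma, counts = st.empirical_variogram(vals, coords, lags)

    def model(h, sill, rng_):
        return sill * (1 - np.exp(-h / rng_))

    ok = counts > 0
    popt, _ = curve_fit(model, centres[ok], gamma[ok], p0=[1.0, 10.0],
                        sigma=1 / np.sqrt(counts[ok]), maxfev=20000)
    assert popt[1] == pytest.approx(r0, rel=0.25)


def test_variogram_degenerate_coords():
    with pytest.raises(ValueError):
        st.empirical_variogram([1.0, 2.0], np.zeros((2, 2)), [0, 1])


def test_statresult_validation():
    with pytest.raises(ValueError):
        st.StatResult("x", 0.0, p=1.5)
    with pytest.raises(ValueError):
        st.StatResult("x", 0.0, p=0.5, ci=(0.95, 2.0, 1.0))
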