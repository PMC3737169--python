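"""Genome scan: design construction, term dropping, F tests, loess smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpqtl import HaplotypeProbSet, build_design, drop_underrepresented, fit_genotype_test
from mpqtl.scan import (
    NEGLOGP_CAP,
    chromosome_cm,
    genome_scan,
    loess_matrix,
    loess_smooth,
    scan_many,
    smooth_neglogp,
)

from conftest import qtl_phenotypes


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def test_design_dimensions_and_lookup(pop):
    X, names = build_design(10, pop["design"], pop["probsA"], pop["probsB"])
    n = len(pop["design"])
    assert X.shape == (n, 16)
    assert names[:2] == ["intercept", "subpop"]
    # row values are exactly the stored parental additive probabilities
    k = 7
    ril = pop["design"]["paternal"].iloc[k]
    ridx = pop["probsA"].index_of([ril])[0]
    expect = np.delete(pop["probsA"].probs[ridx, 10, :], 7)
    assert np.allclose(X[k, 2:9], expect)


def _reference_only_probs(p):
    """Probability set where every RIL is certainly the reference founder AB8."""
    probs = np.zeros_like(p.probs)
    probs[:, :, 7] = 1.0
    return HaplotypeProbSet(p.population, p.ril_ids, p.subpops, p.grid, probs, p.founders)


def test_reference_founder_yields_zero_genotype_columns(pop):
    refA = _reference_only_probs(pop["probsA"])
    refB = _reference_only_probs(pop["probsB"])
    X, _ = build_design(0, pop["design"], refA, refB)
    assert np.allclose(X[:, 2:], 0.0)


@pytest.mark.parametrize(
    "sums, threshold, expect_dropped",
    [((5.0, 4.7), 4.8, ["g2"]), ((4.8, 10.0), 4.8, []), ((0.1, 0.2), 0.0, [])],
)
def test_underrepresented_terms_dropped_strictly_below_threshold(sums, threshold, expect_dropped):
    n = 10
    G = np.column_stack([np.full(n, s / n) for s in sums])
    kept, names, dropped = drop_underrepresented(G, ["g1", "g2"], threshold)
    assert dropped == expect_dropped
    assert kept.shape[1] == 2 - len(expect_dropped)


# ---------------------------------------------------------------------------
# F test
# ---------------------------------------------------------------------------


def test_constant_phenotype_gives_zero_f():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(12), rng.integers(0, 2, 12), rng.random((12, 3))])
    F, df1, df2, nlp = fit_genotype_test(np.full(12, 7.0), X)
    assert F == pytest.approx(0.0, abs=1e-20)
    assert nlp == pytest.approx(0.0, abs=1e-12)


def test_f_statistic_matches_normal_equations_oracle():
    """8-observation toy: F computed independently via explicit normal
    equations (X'X)^-1 X'y and residual sums of squares."""
    X = np.array(
        [
            [1, 0, 0.0, 1.0], [1, 0, 0.5, 0.5], [1, 0, 1.0, 0.0], [1, 0, 0.0, 0.0],
            [1, 1, 1.0, 0.0], [1, 1, 0.0, 1.0], [1, 1, 0.5, 0.0], [1, 1, 0.0, 0.5],
        ]
    )
    y = np.array([3.0, 5.0, 8.0, 2.0, 9.0, 4.0, 7.0, 1.0])

    def rss(M):
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        r = y - M @ beta
        return float(r @ r)

    rss0, rss1 = rss(X[:, :2]), rss(X)
    df1, df2 = 2, 8 - 4
    F_oracle = ((rss0 - rss1) / df1) / (rss1 / df2)
    p_oracle = stats.f.sf(F_oracle, df1, df2)
    F, d1, d2, nlp = fit_genotype_test(y, X)
    assert (d1, d2) == (df1, df2)
    assert F == pytest.approx(F_oracle, rel=1e-10)
    assert nlp == pytest.approx(-np.log10(p_oracle), rel=1e-10)


def test_perfect_fit_capped():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(10), rng.integers(0, 2, 10), rng.random((10, 2))])
    beta = np.array([1.0, 2.0, -3.0, 4.0])
    F, _, _, nlp = fit_genotype_test(X @ beta, X)
    assert nlp == NEGLOGP_CAP


def test_zero_genotype_column_never_changes_f(pop):
    rng = np.random.default_rng(3)
    n = 40
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.random((n, 3))])
    y = rng.random(n)
    F0, *_ = fit_genotype_test(y, X)
    Xz = np.column_stack([X, np.zeros(n)])
    G, names, _ = drop_underrepresented(Xz[:, 2:], ["a", "b", "c", "z"], threshold=1e-12)
    F1, *_ = fit_genotype_test(y, np.column_stack([Xz[:, :2], G]))
    assert F1 == pytest.approx(F0, rel=1e-12)


# ---------------------------------------------------------------------------
# the genome scan
# ---------------------------------------------------------------------------


def test_null_pvalues_uniform_under_permutation(pop):
    """Permuted phenotypes: pointwise p approximately uniform (fraction below
    0.05 within binomial-style bounds, pooled over permutations)."""
    rng = np.random.default_rng(11)
    y, _ = qtl_phenotypes(pop, [], seed=12)
    Y = np.column_stack([rng.permutation(y) for _ in range(20)])
    res = scan_many(pop["design"], pop["probsA"], pop["probsB"], Y)
    p = 10.0 ** (-res["neglogp"][np.isfinite(res["neglogp"])])
    frac = np.mean(p < 0.05)
    assert 0.03 < frac < 0.07


def test_scan_localizes_single_qtl(pop):
    """A QTL at 20% of genetic variance, n=300: the -log10(p) argmax lands
    within 1 cM of the true position in >= 80% of 50 replicates."""
    truth_bp = 1_500_000
    Y, _ = qtl_phenotypes(pop, [("2L", truth_bp, 0.2)], seed=21, n_datasets=50)
    res = scan_many(pop["design"], pop["probsA"], pop["probsB"], Y)
    grid = pop["probsA"].grid
    hits = 0
    for d in range(Y.shape[1]):
        k = np.nanargmax(res["neglogp"][:, d])
        if grid["arm"].iloc[k] == "2L" and abs(grid["pos_bp"].iloc[k] - truth_bp) <= 500_000:
            hits += 1
    assert hits >= 40


def test_scan_deterministic(pop):
    y, _ = qtl_phenotypes(pop, [("2L", 1_500_000, 0.2)], seed=31)
    a = genome_scan(pop["design"], pop["probsA"], pop["probsB"], y)
    b = genome_scan(pop["design"], pop["probsA"], pop["probsB"], y)
    pd.testing.assert_frame_equal(a, b)
    assert {"arm", "pos_bp", "pos_cM", "F", "df1", "df2", "neglog10p", "smoothed",
            "dropped_terms"} <= set(a.columns)
    assert (a["neglog10p"].dropna() >= 0).all()


# ---------------------------------------------------------------------------
# loess smoothing
# ---------------------------------------------------------------------------


def _oracle_loess(x, y, span):
    """Independent tricube local-linear fit: all-pairs distances, nearest-k
    window (ties to the smaller index), weighted polyfit per point."""
    n = len(x)
    k = max(3, int(np.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.lexsort((np.arange(n), d))[:k]
        dmax = d[idx].max()
        w = np.ones(k) if dmax == 0 else (1 - (d[idx] / dmax) ** 3) ** 3
        if w.sum() <= 0:
            w = np.ones(k)
        coeffs = np.polyfit(x[idx], y[idx], 1, w=np.sqrt(w))
        out[i] = np.polyval(coeffs, x[i])
    return out


def test_loess_reproduces_constants_and_lines():
    x = np.linspace(0, 10, 80)
    const = np.full(80, 3.3)
    assert np.allclose(loess_smooth(x, const, 0.2), const, atol=1e-10)
    line = 2.5 * x - 1.0
    assert np.allclose(loess_smooth(x, line, 0.2), line, atol=1e-8)


def test_loess_matches_independent_tricube_oracle():
    rng = np.random.default_rng(5)
    x = np.sort(rng.uniform(0, 100, 200))
    y = np.sin(x / 8) + rng.normal(0, 0.3, 200)
    for span in (0.05, 0.15, 0.4):
        assert np.allclose(loess_smooth(x, y, span), _oracle_loess(x, y, span), atol=1e-6)


def test_loess_agrees_with_statsmodels_lowess():
    """Independent library cross-check: statsmodels' Cleveland lowess with
    zero robustness iterations implements the same degree-1 tricube fit."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    rng = np.random.default_rng(12)
    x = np.sort(rng.uniform(0, 100, 300))
    y = np.sin(x / 8) + rng.normal(0, 0.3, 300)
    for span in (0.1, 0.3):
        theirs = lowess(y, x, frac=span, it=0, return_sorted=False)
        assert np.allclose(loess_smooth(x, y, span), theirs, atol=1e-8)


def test_loess_shift_invariance_and_length():
    rng = np.random.default_rng(6)
    x = np.arange(150.0)
    y = rng.random(150)
    s = loess_smooth(x, y, 0.1)
    assert len(s) == 150
    assert np.allclose(loess_smooth(x, y + 5.0, 0.1), s + 5.0, atol=1e-9)


def test_tiny_span_widened_to_three_points_with_warning():
    x = np.arange(50.0)
    y = x**2
    with pytest.warns(UserWarning, match="widened"):
        S = loess_matrix(x, span=0.01)
    assert np.allclose(S.sum(axis=1), 1.0)


def test_smoothing_is_per_chromosome(pop):
    """Arms of different chromosomes are smoothed independently: a step
    between 2L and 2R must not leak across since they are one chromosome,
    but a synthetic grid with distinct chromosomes keeps the step sharp."""
    grid = pd.DataFrame({
        "arm": ["2L"] * 50 + ["3L"] * 50,
        "pos_bp": list(range(0, 500_000, 10_000)) * 2,
        "pos_cM": list(np.linspace(0, 1, 50)) * 2,
    })
    scanlike = grid.copy()
    scanlike["neglog10p"] = np.r_[np.zeros(50), np.ones(50)]
    out = smooth_neglogp(scanlike, span=0.2)
    assert np.allclose(out["smoothed"].iloc[:50], 0.0, atol=1e-10)
    assert np.allclose(out["smoothed"].iloc[50:], 1.0, atol=1e-10)


def test_same_chromosome_arms_concatenated_on_cm_scale(pop):
    chroms, cm = chromosome_cm(pop["probsA"].grid)
    assert set(chroms) == {"2"}
    assert np.all(np.diff(cm) > 0)  # 2R continues after 2L


def test_coefficient_interval_coverage_under_own_model(pop):
    """Data simulated from the scan's own linear model: 95% CIs for a genotype
    coefficient cover the truth ~95% of the time over 200 simulations."""
    from mpqtl.scan import build_design

    X, _ = build_design(40, pop["design"], pop["probsA"], pop["probsB"])
    rng = np.random.default_rng(9)
    beta = rng.normal(0, 2.0, X.shape[1])
    n, p = X.shape
    XtXi = np.linalg.pinv(X.T @ X)
    cover = 0
    tcrit = stats.t.ppf(0.975, n - p)
    for s in range(200):
        y = X @ beta + rng.normal(0, 3.0, n)
        bhat = XtXi @ X.T @ y
        resid = y - X @ bhat
        sigma2 = resid @ resid / (n - p)
        se = np.sqrt(sigma2 * XtXi[5, 5])
        if abs(bhat[5] - beta[5]) <= tcrit * se:
            cover += 1
    assert 0.90 <= cover / 200 <= 0.99
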