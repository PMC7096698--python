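"""Statistical stack: oracles from independent implementations and closed forms."""

import itertools

import numpy as np
import pytest
from scipy.linalg import sqrtm

from psmdkit import (
    CollinearityError,
    DegenerateDataError,
    delong_compare,
    dominance_analysis,
    fisher_rz_compare,
    holm_bonferroni,
    importance_analysis,
    relative_weights,
    robust_correlation,
    robust_fit,
    roc_auc,
)


def _orthogonal_design(rng, n, p):
    """Columns exactly orthogonal, zero-mean, unit-SD (QR of a centred matrix)."""
    g = rng.normal(size=(n, p))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    return q / q.std(axis=0, ddof=1)


class TestRobustFit:
    def test_exact_linear_data_recovers_slopes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = 1.5 + X @ np.array([2.0, -0.7, 0.3])
        fit = robust_fit(y, X)
        assert np.allclose(fit.params, [1.5, 2.0, -0.7, 0.3], atol=1e-10)

    def test_matches_ols_on_clean_gaussian_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 2))
        y = 2.0 + X @ np.array([1.0, -0.5]) + rng.normal(0, 0.2, size=500)
        fit = robust_fit(y, X)
        ols = np.linalg.lstsq(np.column_stack([np.ones(500), X]), y, rcond=None)[0]
        assert np.allclose(fit.params, ols, rtol=0.01, atol=0.01)

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        y = 1.0 + X @ np.array([0.8, -1.2]) + rng.standard_t(3, size=200)
        fit = robust_fit(y, X)
        ref = sm.RLM(y, sm.add_constant(X), M=sm.robust.norms.HuberT()).fit()
        assert np.allclose(fit.params, ref.params, rtol=1e-3, atol=1e-4)

    def test_reduces_to_ols_at_huge_tuning_constant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = X @ np.array([1.0, 2.0]) + rng.lognormal(0, 1, 100)
        fit = robust_fit(y, X, tuning_constant=1e6)
        ols = np.linalg.lstsq(np.column_stack([np.ones(100), X]), y, rcond=None)[0]
        assert np.allclose(fit.params, ols, rtol=1e-6)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        with pytest.raises(CollinearityError):
            robust_fit(rng.normal(size=100), np.column_stack([x, 2 * x]))

    def test_summary_renders(self):
        rng = np.random.default_rng(5)
        fit = robust_fit(rng.normal(size=50), rng.normal(size=(50, 1)), names=["slope"])
        assert "slope" in fit.summary()


class TestRobustCorrelation:
    def test_identity_gives_one(self):
        x = np.arange(20.0)
        r, p = robust_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_percbend(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        y[:4] += 15  # outliers the bend should absorb
        r, p = robust_correlation(x, y)
        ref = pg.corr(x, y, method="percbend")
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_null_and_correlated_calibration(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 10_000))
        r, _ = robust_correlation(x, y)
        assert abs(r) < 0.03
        z = 0.5 * x + np.sqrt(1 - 0.25) * y
        r_pb, _ = robust_correlation(x, z)
        assert r_pb == pytest.approx(np.corrcoef(x, z)[0, 1], abs=0.05)

    def test_zero_spread_raises(self):
        with pytest.raises(DegenerateDataError):
            robust_correlation(np.ones(10), np.arange(10.0))


class TestFisherRz:
    def test_equal_correlations(self):
        z, p = fisher_rz_compare(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, p1 = fisher_rz_compare(0.5, 103, 0.3, 103)
        z2, p2 = fisher_rz_compare(0.3, 103, 0.5, 103)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_closed_form_value(self):
        z, _ = fisher_rz_compare(0.5, 103, 0.3, 103)
        assert z == pytest.approx(1.696, abs=1e-3)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_rz_compare(1.0, 50, 0.3, 50)


def _brute_force_dominance(y, X):
    """Independent oracle: enumerate subsets, average incremental R² by hand."""
    n, p = X.shape
    Zx = (X - X.mean(0)) / X.std(0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)

    def r2_of(cols):
        if not cols:
            return 0.0
        A = np.column_stack([np.ones(n), Zx[:, list(cols)]])
        beta, *_ = np.linalg.lstsq(A, zy, rcond=None)
        resid = zy - A @ beta
        return 1.0 - resid @ resid / (zy @ zy)

    dw = np.zeros(p)
    for i in range(p):
        rest = [j for j in range(p) if j != i]
        size_means = []
        for k in range(p):
            incs = [
                r2_of(set(s) | {i}) - r2_of(set(s))
                for s in itertools.combinations(rest, k)
            ]
            size_means.append(np.mean(incs))
        dw[i] = np.mean(size_means)
    return dw


class TestImportance:
    def test_single_predictor_dw_is_simple_r2(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=120)
        y = 0.6 * x + rng.normal(size=120)
        res = dominance_analysis(y, x[:, None], names=["x"])
        assert res.dominance_weights[0] == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, rel=1e-10
        )

    @pytest.mark.parametrize("p", [3, 4])
    def test_dominance_equals_brute_force_oracle(self, p):
        rng = np.random.default_rng(9 + p)
        L = rng.normal(size=(p, p))
        X = rng.normal(size=(150, p)) @ L  # correlated design
        y = X @ rng.normal(size=p) + rng.normal(size=150)
        res = dominance_analysis(y, X)
        assert np.allclose(res.dominance_weights, _brute_force_dominance(y, X), atol=1e-10)
        assert res.dominance_weights.sum() == pytest.approx(res.r_squared, abs=1e-9)

    def test_orthogonal_design_collapses_to_zero_order_r2(self):
        rng = np.random.default_rng(11)
        X = _orthogonal_design(rng, 200, 3)
        y = X @ np.array([0.7, 0.4, -0.2]) + rng.normal(size=200)
        res = importance_analysis(y, X)
        r2_zero = np.array([np.corrcoef(X[:, j], y)[0, 1] ** 2 for j in range(3)])
        assert np.allclose(res.dominance_weights, r2_zero, atol=1e-10)
        assert np.allclose(res.relative_weights, r2_zero, atol=1e-10)
        assert np.allclose(res.betas**2, r2_zero, atol=1e-10)

    def test_relative_weights_sum_and_second_implementation(self):
        """RW sums to R² and matches an independently coded route via sqrtm."""
        rng = np.random.default_rng(12)
        base = rng.normal(size=(300, 2))
        X = np.column_stack([base[:, 0], 0.5 * base[:, 0] + np.sqrt(0.75) * base[:, 1]])
        y = X @ np.array([0.5, 0.3]) + rng.normal(size=300)
        res = relative_weights(y, X)
        assert res.relative_weights.sum() == pytest.approx(res.r_squared, abs=1e-9)
        Zx = (X - X.mean(0)) / X.std(0, ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        Rxx = Zx.T @ Zx / (len(y) - 1)
        rxy = Zx.T @ zy / (len(y) - 1)
        lam = np.real(sqrtm(Rxx))
        beta_star = np.linalg.solve(lam, rxy)
        rw_ref = (lam**2) @ (beta_star**2)
        assert np.allclose(res.relative_weights, rw_ref, atol=1e-8)
        assert res.pct_contribution.sum() == pytest.approx(100.0, abs=1e-6)

    def test_enumeration_bound(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 16))
        with pytest.raises(ValueError, match="15"):
            dominance_analysis(rng.normal(size=40), X)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc(np.ones(20), np.arange(20) % 2) == 0.5

    def test_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(14)
        scores = rng.integers(0, 30, size=200).astype(float)  # many ties
        labels = rng.random(200) < 0.4
        pos, neg = scores[labels], scores[~labels]
        u = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        )
        assert roc_auc(scores, labels) == pytest.approx(u / (pos.size * neg.size))
        skl = pytest.importorskip("sklearn.metrics")
        assert roc_auc(scores, labels) == pytest.approx(
            skl.roc_auc_score(labels, scores)
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        assert roc_auc(np.exp(scores), labels) == pytest.approx(
            roc_auc(scores, labels)
        )

    def test_single_class_raises(self):
        with pytest.raises(DegenerateDataError):
            roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_self_comparison(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.5
        cmp = delong_compare(scores, scores, labels)
        assert cmp.z == 0.0 and cmp.p == 1.0 and cmp.degenerate

    def test_power_on_separated_aucs(self):
        """AUC 0.9 vs 0.6 at n=200 is detected at p<0.01 in >=95% of replicates."""
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            y = np.repeat([0, 1], 100)
            a = np.where(y == 1, rng.normal(1.81, 1, 200), rng.normal(0, 1, 200))
            b = np.where(y == 1, rng.normal(0.36, 1, 200), rng.normal(0, 1, 200))
            hits += delong_compare(a, b, y).p < 0.01
        assert hits / 200 >= 0.95

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(17)
        y = rng.random(100) < 0.5
        s = rng.normal(size=100) + y
        cmp = delong_compare(s, rng.normal(size=100), y)
        assert cmp.ci_a[0] < cmp.auc_a < cmp.ci_a[1]


class TestHolm:
    def test_single_p(self):
        adj, rej = holm_bonferroni([0.03])
        assert adj[0] == 0.03 and rej[0]

    def test_hand_computed_step_down(self):
        adj, rej = holm_bonferroni([0.01, 0.02, 0.03], alpha=0.05)
        assert np.allclose(adj, [0.03, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        adj, rej = holm_bonferroni(np.ones(5))
        assert (adj == 1).all() and not rej.any()

    def test_matches_statsmodels(self):
        smm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(18)
        p = rng.random(12)
        adj, rej = holm_bonferroni(p, alpha=0.05)
        ref_rej, ref_adj, *_ = smm.multipletests(p, alpha=0.05, method="holm")
        assert np.allclose(adj, ref_adj)
        assert (rej == ref_rej).all()

    def test_no_less_powerful_than_bonferroni(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = rng.random(8)
            _, holm_rej = holm_bonferroni(p, alpha=0.05)
            bonf_rej = p < 0.05 / len(p)
            assert (holm_rej | ~bonf_rej).all()  # Holm rejects whatever Bonferroni does
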