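"""Multinomial fits and the likelihood-ratio test against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mexplorer.mnlogit import (
    PredictorEncoding,
    crosstab_counts,
    encode_predictor,
    fit_alternative,
    fit_null,
    lr_test,
)
from mexplorer.regdata import BASELINE_CLASS, BASELINE_LABEL, ProcessResponse, RegulatoryMatrix

from conftest import make_response


# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------


def random_instance(rng, N, C, K):
    """Random response + predictor with every class and level populated."""
    y = rng.integers(0, C, N)
    y[:C] = np.arange(C)
    codes = rng.integers(0, K + 1, N)
    codes[C : C + K + 1] = np.arange(K + 1)
    genes = [f"g{i}" for i in range(N)]
    classes = [f"c{j}" for j in range(C - 1)] + [BASELINE_CLASS]
    resp = ProcessResponse(classes, pd.Series([classes[v] for v in y], index=genes))
    enc = PredictorEncoding("tfX", [f"lev{k}" for k in range(1, K + 1)], codes)
    return resp, enc


def crosstab_loglik_oracle(resp, enc):
    """Saturated cross-tab log-likelihood computed independently with pandas."""
    df = pd.DataFrame({"y": resp.codes(), "x": enc.level_codes})
    tab = pd.crosstab(df["x"], df["y"])
    total = 0.0
    for _, row in tab.iterrows():
        row_tot = row.sum()
        for n in row:
            if n > 0:
                total += n * np.log(n / row_tot)
    return total


def binomial_newton_oracle(y01, x01, tol=1e-12, max_iter=100):
    """Independently coded Newton-Raphson binary logistic fit; returns the
    maximized log-likelihood."""
    X = np.column_stack([np.ones_like(x01, dtype=float), x01.astype(float)])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y01 - p)
        W = p * (1 - p)
        H = X.T @ (W[:, None] * X)
        step = np.linalg.solve(H + 1e-12 * np.eye(2), grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-15, 1 - 1e-15)
    return float(np.sum(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# encode_predictor
# ---------------------------------------------------------------------------


class TestEncodePredictor:
    def test_levels_present_counted(self):
        df = pd.DataFrame(
            {"tf": ["up", "TFBS", BASELINE_LABEL, "up", BASELINE_LABEL]},
            index=[f"g{i}" for i in range(5)],
        )
        enc = encode_predictor(RegulatoryMatrix(df), "tf")
        assert enc.K == 2
        assert enc.levels == ["up", "TFBS"]
        assert "down" in enc.dropped_levels

    def test_all_baseline_gives_k0(self):
        df = pd.DataFrame({"tf": [BASELINE_LABEL] * 4}, index=list("abcd"))
        enc = encode_predictor(RegulatoryMatrix(df), "tf")
        assert enc.K == 0

    def test_all_eight_classes_gives_k8(self):
        from mexplorer.regdata import EVIDENCE_CLASSES

        labels = list(EVIDENCE_CLASSES)  # baseline + 8
        df = pd.DataFrame({"tf": labels}, index=[f"g{i}" for i in range(9)])
        enc = encode_predictor(RegulatoryMatrix(df), "tf")
        assert enc.K == 8

    def test_indicator_vectors_mutually_exclusive(self):
        df = pd.DataFrame(
            {"tf": ["up", "down", BASELINE_LABEL]}, index=list("abc")
        )
        enc = encode_predictor(RegulatoryMatrix(df), "tf")
        # integer coding: one level per gene by construction
        assert set(enc.level_codes) <= {0, 1, 2}


# ---------------------------------------------------------------------------
# fit_null
# ---------------------------------------------------------------------------


class TestFitNull:
    def test_uniform_closed_form(self):
        resp = make_response({"a": 25, "b": 25, "c": 25, BASELINE_CLASS: 25})
        fit = fit_null(resp)
        assert fit.loglik == pytest.approx(100 * np.log(0.25), abs=1e-9)
        assert fit.n_params == 3

    def test_skewed_counts_closed_form(self):
        resp = make_response({"a": 10, "b": 30, BASELINE_CLASS: 60})
        fit = fit_null(resp)
        expected = 10 * np.log(0.1) + 30 * np.log(0.3) + 60 * np.log(0.6)
        assert fit.loglik == pytest.approx(expected, abs=1e-9)
        assert fit.coef[0, 0] == pytest.approx(np.log(10 / 60))
        assert fit.coef[0, 1] == pytest.approx(np.log(30 / 60))

    def test_binomial_reduction(self):
        """With C=2 the null fit equals the intercept-only binary logistic
        log-likelihood n1 log(n1/N) + n0 log(n0/N)."""
        resp = make_response({"a": 18, BASELINE_CLASS: 42})
        fit = fit_null(resp)
        expected = 18 * np.log(18 / 60) + 42 * np.log(42 / 60)
        assert fit.loglik == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# fit_alternative
# ---------------------------------------------------------------------------


class TestFitAlternative:
    def test_small_instance_matches_crosstab_oracle(self):
        """N=8, C=2, K=1: class1 has 3 of 4 genes exposed, baseline 1 of 4;
        the MLE log-likelihood equals the saturated cross-tab closed form."""
        genes = [f"g{i}" for i in range(8)]
        labels = ["a"] * 4 + [BASELINE_CLASS] * 4
        resp = ProcessResponse(["a", BASELINE_CLASS], pd.Series(labels, index=genes))
        codes = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        enc = PredictorEncoding("tf", ["up"], codes)
        fit = fit_alternative(resp, enc)
        # cells: exposed (3 a, 1 base), unexposed (1 a, 3 base)
        expected = (
            3 * np.log(3 / 4) + 1 * np.log(1 / 4) + 1 * np.log(1 / 4) + 3 * np.log(3 / 4)
        )
        assert fit.loglik == pytest.approx(expected, abs=1e-10)

    def test_independent_predictor_slopes_vanish(self, rng):
        """At N=1e5 with predictor independent of response, slope estimates
        shrink toward zero and the LR gain is negligible per observation."""
        N = 100_000
        resp, enc = random_instance(rng, N, C=3, K=2)
        fit1 = fit_alternative(resp, enc)
        fit0 = fit_null(resp)
        assert np.abs(fit1.coef[1:, :]).max() < 0.05
        assert (fit1.loglik - fit0.loglik) / N < 1e-4

    def test_k0_rejected(self):
        resp = make_response({"a": 3, BASELINE_CLASS: 3})
        enc = PredictorEncoding("tf", [], np.zeros(6, dtype=np.int64))
        with pytest.raises(ValueError, match="K=0"):
            fit_alternative(resp, enc)

    def test_newton_and_crosstab_agree(self, rng):
        for _ in range(10):
            resp, enc = random_instance(rng, 120, C=4, K=3)
            auto = fit_alternative(resp, enc, method="auto")
            newton = fit_alternative(resp, enc, method="newton")
            assert newton.converged
            assert auto.loglik == pytest.approx(newton.loglik, abs=1e-6)

    def test_binomial_reduction_matches_newton_oracle(self, rng):
        """C=2 fits agree with an independently coded binary logistic
        Newton-Raphson fit to at least 6 decimals in log-likelihood."""
        for _ in range(10):
            N = int(rng.integers(40, 200))
            resp, enc = random_instance(rng, N, C=2, K=1)
            fit = fit_alternative(resp, enc)
            y01 = 1 - resp.codes()  # class 'c0' = 1, baseline = 0
            oracle = binomial_newton_oracle(y01, (enc.level_codes == 1))
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    @settings(max_examples=40)
    @given(
        n=st.integers(30, 200),
        C=st.integers(2, 7),
        K=st.integers(1, 8),
        seed=st.integers(0, 10_000),
    )
    def test_crosstab_oracle_equivalence_property(self, n, C, K, seed):
        """Random non-degenerate instances: |l1 - saturated cross-tab| <= 1e-6."""
        rng = np.random.default_rng(seed)
        n = max(n, C + K + 2)
        resp, enc = random_instance(rng, n, C, K)
        fit = fit_alternative(resp, enc)
        assert abs(fit.loglik - crosstab_loglik_oracle(resp, enc)) <= 1e-6

    @settings(max_examples=30)
    @given(
        n=st.integers(20, 150),
        C=st.integers(2, 5),
        K=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_nesting_property(self, n, C, K, seed):
        """l1 >= l0 - 1e-6 on every instance."""
        rng = np.random.default_rng(seed)
        n = max(n, C + K + 2)
        resp, enc = random_instance(rng, n, C, K)
        assert fit_alternative(resp, enc).loglik >= fit_null(resp).loglik - 1e-6

    def test_gene_permutation_invariance(self, rng):
        resp, enc = random_instance(rng, 80, C=3, K=2)
        perm = rng.permutation(80)
        resp_p = ProcessResponse(
            list(resp.classes), resp.assignment.iloc[perm], resp.baseline
        )
        enc_p = PredictorEncoding(enc.tf, list(enc.levels), enc.level_codes[perm])
        a, b = fit_alternative(resp, enc), fit_alternative(resp_p, enc_p)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-12)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-12)

    def test_baseline_relabel_preserves_loglik_and_lr(self, rng):
        """Choosing a different response class as baseline changes the
        coefficients but not l-hat or the LR statistic."""
        resp, enc = random_instance(rng, 100, C=3, K=2)
        # swap roles: make 'c0' the baseline, old baseline a named class
        relabeled = resp.assignment.replace(
            {"c0": BASELINE_CLASS, BASELINE_CLASS: "c0"}
        )
        resp2 = ProcessResponse(["c0", "c1", BASELINE_CLASS], relabeled)
        s1 = lr_test(fit_null(resp), fit_alternative(resp, enc)).statistic
        s2 = lr_test(fit_null(resp2), fit_alternative(resp2, enc)).statistic
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_separation_flagged_and_capped(self):
        """An evidence level seen only in one response class drives its
        coefficient to infinity; it is capped and flagged, and the LR
        statistic stays finite."""
        genes = [f"g{i}" for i in range(12)]
        labels = ["a"] * 4 + [BASELINE_CLASS] * 8
        resp = ProcessResponse(["a", BASELINE_CLASS], pd.Series(labels, index=genes))
        codes = np.array([1, 1, 1, 1] + [0] * 8)  # level fully inside class a
        enc = PredictorEncoding("tf", ["up"], codes)
        fit = fit_alternative(resp, enc)
        assert fit.separated_levels
        assert np.abs(fit.coef).max() <= 30
        assert np.isfinite(fit.loglik)
        test = lr_test(fit_null(resp), fit)
        assert np.isfinite(test.statistic) and test.p < 0.01

    def test_fitted_probabilities_are_distributions(self, rng):
        resp, enc = random_instance(rng, 60, C=4, K=2)
        fit = fit_alternative(resp, enc)
        p = fit.predict_proba(enc.level_codes)
        assert np.all(p > 0) and np.all(p < 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# lr_test
# ---------------------------------------------------------------------------


class TestLRTest:
    def test_identical_logliks_give_p_one(self, rng):
        resp = make_response({"a": 10, BASELINE_CLASS: 10})
        null = fit_null(resp)
        alt = fit_null(resp)
        alt.n_params += 1  # pretend one extra parameter, same fit
        res = lr_test(null, alt)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_known_chi_square_tail(self):
        """A statistic of 10.83 on 1 df sits at the classical p ~ 0.000998."""
        resp = make_response({"a": 10, BASELINE_CLASS: 10})
        null = fit_null(resp)
        alt = fit_null(resp)
        alt.n_params += 1
        alt.loglik = null.loglik + 10.83 / 2
        res = lr_test(null, alt)
        assert res.p == pytest.approx(0.000998, rel=1e-3)

    def test_df_accounting(self, rng):
        resp, enc = random_instance(rng, 100, C=4, K=3)
        res = lr_test(fit_null(resp), fit_alternative(resp, enc))
        assert res.df == (4 - 1) * 3

    def test_mismatched_fits_rejected(self, rng):
        resp1, enc1 = random_instance(rng, 50, C=3, K=2)
        resp2, _ = random_instance(rng, 60, C=3, K=2)
        with pytest.raises(ValueError, match="different numbers of genes"):
            lr_test(fit_null(resp2), fit_alternative(resp1, enc1))

    def test_null_calibration_ks(self, rng):
        """Under a shuffled (independent) predictor, LR p-values are U(0,1):
        KS test not significant at 1% over 1000 replicates."""
        N, C = 300, 3
        resp, enc = random_instance(rng, N, C, K=2)
        null = fit_null(resp)
        codes = enc.level_codes.copy()
        pvals = np.empty(1000)
        for i in range(1000):
            shuffled = PredictorEncoding(
                enc.tf, list(enc.levels), rng.permutation(codes)
            )
            pvals[i] = lr_test(null, fit_alternative(resp, shuffled)).p
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
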