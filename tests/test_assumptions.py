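"""Assumption checks: polychoric, factor fit, bifactor, Mokken, IIO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promkit.assumptions import (
    bifactor_indices,
    bifactor_indices_from_loadings,
    bvn_cdf,
    iio_ht,
    ht_band,
    mokken_coefficients,
    monotonicity_check,
    polychoric_matrix,
    polychoric_pair,
    residual_correlations,
    run_assumptions,
    single_factor_fit,
)
from promkit.synthetic import BankSpec, generate_item_bank, simulate_responses


def ordinalize(z, cuts=(-1.2, -0.4, 0.5, 1.3)):
    return np.digitize(z, cuts)


class TestPolychoric:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = ordinalize(rng.normal(size=500))
        R, _ = polychoric_matrix(np.column_stack([x, x]))
        assert R[0, 1] > 0.97

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = ordinalize(rng.normal(size=(5000, 2)))
        assert abs(polychoric_pair(X[:, 0], X[:, 1])) < 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_known_rho_recovery(self, rho):
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=10_000)
        est = polychoric_pair(ordinalize(z[:, 0]), ordinalize(z[:, 1]))
        assert abs(est - rho) < 0.05

    def test_dichotomized_recovery(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=10_000)
        est = polychoric_pair((z[:, 0] > 0.2).astype(int), (z[:, 1] > -0.3).astype(int))
        assert 0.55 <= est <= 0.65

    def test_bvn_cdf_against_scipy(self):
        from scipy.stats import multivariate_normal

        for rho in (-0.8, 0.0, 0.5):
            mv = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            for x, y in [(-1.0, 0.3), (0.0, 0.0), (1.5, -2.0)]:
                assert bvn_cdf(x, y, rho) == pytest.approx(mv.cdf([x, y]), abs=1e-6)


class TestSingleFactorFit:
    def test_rank_one_matrix_fits_exactly(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        loadings, fit = single_factor_fit(R, n_persons=500)
        assert fit["srmr"] < 1e-4
        assert fit["cfi"] > 0.999
        assert np.allclose(np.abs(loadings), lam, atol=1e-3)

    def test_one_factor_data_good_fit(self):
        bank = generate_item_bank(BankSpec(8, name="f"), seed=3)
        rng = np.random.default_rng(0)
        resp = simulate_responses(bank, rng.normal(size=5000), seed=4)
        R, _ = polychoric_matrix(resp.data)
        _, fit = single_factor_fit(R, 5000)
        assert fit["cfi"] >= 0.95
        assert fit["srmr"] <= 0.08

    def test_two_orthogonal_clusters_misfit(self):
        rng = np.random.default_rng(2)
        n = 3000
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        Y = np.empty((n, 8))
        for j in range(8):
            f = f1 if j < 4 else f2
            Y[:, j] = 0.8 * f + 0.6 * rng.normal(size=n)
        R, _ = polychoric_matrix(ordinalize(Y))
        _, fit = single_factor_fit(R, n)
        assert not (fit["cfi_good"] and fit["tli_good"] and fit["rmsea_good"] and fit["srmr_good"])

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            single_factor_fit(np.eye(2), 100)


class TestResidualCorrelations:
    def test_perfect_one_factor_no_flags(self):
        lam = np.full(8, 0.7)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        flagged, n_pairs = residual_correlations(R, lam)
        assert flagged == []
        assert n_pairs == 28

    def test_locally_dependent_pair_flagged(self):
        rng = np.random.default_rng(5)
        n = 4000
        g = rng.normal(size=n)
        e_shared = rng.normal(size=n)  # extra correlated error for items 2 and 5
        Y = np.empty((n, 8))
        for j in range(8):
            e = 0.55 * rng.normal(size=n)
            if j in (2, 5):
                e = 0.4 * rng.normal(size=n) + 0.55 * e_shared
            Y[:, j] = 0.7 * g + e
        X = ordinalize(Y)
        R, _ = polychoric_matrix(X)
        lam, _ = single_factor_fit(R, n)
        flagged, n_pairs = residual_correlations(R, lam)
        assert [(i, j) for i, j, _ in flagged] == [(2, 5)]

    def test_report_format(self):
        from promkit.assumptions import AssumptionReport

        rep = AssumptionReport(
            cfi=1, tli=1, rmsea=0, srmr=0, loadings=np.ones(8), ecv=1, omega_h=1,
            residual_pairs=[(0, 1, 0.27)], n_pairs=28, H=1, Hi=np.ones(8),
            monotonicity_violations=np.zeros(8, dtype=int), HT=0.5,
        )
        assert rep.residual_flag_summary == "1 (3.6)"


class TestBifactor:
    def test_equal_general_and_group_loadings_give_half(self):
        g = np.full(6, 0.5)
        s = np.zeros((6, 2))
        s[:3, 0] = 0.5
        s[3:, 1] = 0.5
        ecv, _ = bifactor_indices_from_loadings(g, s)
        assert ecv == pytest.approx(0.5)

    def test_pure_general_factor(self):
        g = np.full(6, 0.7)
        s = np.zeros((6, 2))
        ecv, omega_h = bifactor_indices_from_loadings(g, s)
        assert ecv == pytest.approx(1.0)
        # omega_h = (6*.7)^2 / ((6*.7)^2 + 6*(1-.49))
        assert omega_h == pytest.approx(17.64 / (17.64 + 6 * 0.51))

    def test_essentially_unidimensional_supportive(self):
        rng = np.random.default_rng(4)
        n = 3000
        g, s1, s2 = rng.normal(size=(3, n))
        Y = np.empty((n, 12))
        for j in range(12):
            s = s1 if j < 6 else s2
            e = rng.normal(size=n) * np.sqrt(1 - 0.49 - 0.09)
            Y[:, j] = 0.7 * g + 0.3 * s + e
        ecv, omega_h = bifactor_indices(responses=ordinalize(Y))
        assert ecv >= 0.70
        assert omega_h >= 0.70

    def test_unidimensional_data_high_ecv(self):
        bank = generate_item_bank(BankSpec(8, name="u"), seed=3)
        rng = np.random.default_rng(0)
        resp = simulate_responses(bank, rng.normal(size=2000), seed=4)
        ecv, omega_h = bifactor_indices(responses=resp.data)
        assert ecv >= 0.70
        assert omega_h >= 0.70


class TestMokken:
    def test_guttman_pattern_gives_one(self):
        G = np.tril(np.ones((6, 5), dtype=int))
        X = np.vstack([G, np.zeros((1, 5), dtype=int)])
        assert mokken_coefficients(X)["H"] == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 5, size=(5000, 6))
        assert abs(mokken_coefficients(X)["H"]) < 0.05

    def test_high_discrimination_acceptable(self):
        bank = generate_item_bank(BankSpec(8, alpha_range=(2.5, 2.5), name="h"), seed=2)
        rng = np.random.default_rng(1)
        resp = simulate_responses(bank, rng.normal(size=3000), seed=5)
        assert mokken_coefficients(resp.data)["H"] >= 0.5

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_person_reordering(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 4, size=(60, 5))
        if np.any(X.std(axis=0) == 0):
            return
        perm = rng.permutation(60)
        assert mokken_coefficients(X)["H"] == pytest.approx(
            mokken_coefficients(X[perm])["H"]
        )

    def test_zero_variance_item_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 4, size=(100, 4))
        X[:, 1] = 2
        out = mokken_coefficients(X)
        assert out["excluded_items"] == [1]


class TestMonotonicity:
    def test_grm_data_clean(self, responses2000):
        resp, _ = responses2000
        out = monotonicity_check(resp.data)
        assert out["checkable"]
        assert out["violations"].sum() == 0

    def test_inverted_item_detected(self, responses2000):
        resp, _ = responses2000
        X = resp.data.copy()
        X[:, 3] = 4 - X[:, 3]
        out = monotonicity_check(X)
        assert out["violations"][3] > 0

    def test_single_group_not_checkable(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(30, 4))
        out = monotonicity_check(X, min_group_size=50)
        assert not out["checkable"]


class TestIIO:
    def test_separated_thresholds_high_accuracy(self):
        # widely separated item locations, high discrimination: orderable
        from promkit import ItemParameters

        alphas = np.full(6, 3.0)
        betas = [np.array([c - 0.3, c, c + 0.3]) for c in np.linspace(-2.4, 2.4, 6)]
        bank = ItemParameters(alphas, betas)
        rng = np.random.default_rng(6)
        resp = simulate_responses(bank, rng.normal(size=1500), seed=7)
        assert iio_ht(resp.data) >= 0.5

    @pytest.mark.parametrize(
        "value,band",
        [(0.036, "inaccurate ordering"), (0.356, "low accuracy"), (0.495, "medium accuracy"), (0.541, "high accuracy")],
    )
    def test_bands(self, value, band):
        assert ht_band(value) == band

    def test_identical_persons_undefined(self):
        X = np.tile(np.array([[1, 2, 3]]), (10, 1))
        assert np.isnan(iio_ht(X))


def test_run_assumptions_bundles_everything(responses2000):
    resp, _ = responses2000
    rep = run_assumptions(resp.data[:800])
    v = rep.verdicts()
    assert v["H_acceptable"] and v["ecv_supportive"]
    assert rep.n_pairs == 13 * 12 // 2
    assert rep.monotonicity_violations.shape == (13,)
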