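"""Synthetic study generator: banks, traits, responses, DIF, sampling."""

import numpy as np
import pandas as pd
import pytest

from promkit.synthetic import (
    BankSpec,
    DIFSpec,
    PopulationSpec,
    default_covariate_margins,
    draw_reference_sample,
    generate_item_bank,
    marginal_category_probabilities,
    simulate_legacy_scale,
    simulate_responses,
    simulate_thetas,
)


class TestGenerateItemBank:
    def test_degenerate_ranges_force_values(self):
        spec = BankSpec(1, n_categories=2, alpha_range=(1, 1), threshold_span=(0, 0))
        bank = generate_item_bank(spec, seed=0)
        assert bank.alphas[0] == pytest.approx(1.0)
        assert bank.betas[0][0] == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_under_seed(self):
        spec = BankSpec(7, name="d")
        a = generate_item_bank(spec, seed=33)
        b = generate_item_bank(spec, seed=33)
        assert np.array_equal(a.alphas, b.alphas)
        assert all(np.array_equal(x, y) for x, y in zip(a.betas, b.betas))

    def test_threshold_rows_strictly_increasing(self):
        bank = generate_item_bank(BankSpec(13, n_categories=5), seed=4)
        assert len(bank.betas) == 13
        for b in bank.betas:
            assert b.size == 4
            assert np.all(np.diff(b) > 0)

    def test_invalid_alpha_range_rejected(self):
        with pytest.raises(ValueError):
            BankSpec(5, alpha_range=(0.0, 2.0))

    def test_subset_outside_bank_rejected(self):
        with pytest.raises(ValueError):
            BankSpec(5, short_form_items=(0, 7))


class TestSimulateThetas:
    def test_standard_normal_moments(self):
        pop = PopulationSpec(n_persons=10_000)
        df = simulate_thetas(pop, seed=11)
        assert abs(df.theta.mean()) < 0.05
        assert 0.97 <= df.theta.std() <= 1.03

    def test_full_ceiling(self):
        pop = PopulationSpec(n_persons=200, ceiling_mass=1.0, ceiling_direction="symptom")
        df = simulate_thetas(pop, seed=1)
        # all persons in the narrow extreme component at -2.5
        assert df.theta.mean() < -2.0
        assert df.theta.std() < 0.4

    def test_seed_sensitivity(self):
        pop = PopulationSpec(n_persons=100)
        a = simulate_thetas(pop, seed=1).theta
        b = simulate_thetas(pop, seed=2).theta
        assert not np.allclose(a, b)

    def test_bad_margins_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(covariate_margins={"sex": {"m": 0.6, "f": 0.6}})

    def test_covariates_follow_margins(self):
        margins = default_covariate_margins()
        pop = PopulationSpec(n_persons=20_000, covariate_margins=margins)
        df = simulate_thetas(pop, seed=3)
        for cov, m in margins.items():
            props = df[cov].value_counts(normalize=True)
            for level, pi in m.items():
                assert abs(props.get(level, 0) - pi) < 0.02


class TestSimulateResponses:
    def test_deterministic_limit(self):
        from promkit import ItemParameters

        params = ItemParameters([80.0], [np.array([0.0])])
        resp = simulate_responses(params, np.array([2.0]), seed=0)
        assert resp.data[0, 0] == 1  # top category with probability ~1

    def test_marginal_frequencies_match_quadrature_oracle(self):
        from promkit import ItemParameters

        params = ItemParameters([1.7], [np.array([-1.0, 0.0, 1.0, 2.0])])
        rng = np.random.default_rng(8)
        resp = simulate_responses(params, rng.normal(size=5000), seed=21)
        observed = np.bincount(resp.data[:, 0], minlength=5) / 5000
        expected = marginal_category_probabilities(params, 0)
        assert np.abs(observed - expected).max() < 0.02

    def test_uniform_dif_shifts_only_target_item(self):
        bank = generate_item_bank(BankSpec(5, name="d"), seed=9)
        rng = np.random.default_rng(10)
        n = 5000
        persons = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "theta": rng.normal(size=n),
                "grp": np.where(np.arange(n) % 2 == 0, "a", "b"),
            }
        )
        dif = [DIFSpec(2, "grp", "b", uniform_shift=0.5)]
        with_dif = simulate_responses(bank, persons, dif, seed=3)
        without = simulate_responses(bank, persons, None, seed=3)
        b_mask = (persons.grp == "b").to_numpy()
        # positive threshold shift lowers the focal group's item mean
        assert (
            with_dif.data[b_mask, 2].mean() < without.data[b_mask, 2].mean() - 0.05
        )
        # same seed, untouched items and reference group identical
        others = [0, 1, 3, 4]
        assert np.array_equal(with_dif.data[:, others], without.data[:, others])
        assert np.array_equal(with_dif.data[~b_mask, 2], without.data[~b_mask, 2])

    def test_zero_shift_reproduces_no_dif_exactly(self):
        bank = generate_item_bank(BankSpec(4, name="z"), seed=2)
        persons = pd.DataFrame(
            {"person_id": [0, 1, 2], "theta": [0.0, 1.0, -1.0], "g": ["x", "y", "x"]}
        )
        dif = [DIFSpec(1, "g", "y", uniform_shift=0.0, alpha_multiplier=1.0)]
        a = simulate_responses(bank, persons, dif, seed=5)
        b = simulate_responses(bank, persons, None, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_nonfinite_theta_rejected(self):
        bank = generate_item_bank(BankSpec(3), seed=1)
        with pytest.raises(ValueError):
            simulate_responses(bank, np.array([0.0, np.inf]), seed=0)


class TestLegacyScale:
    def test_perfect_correlation(self):
        theta = np.random.default_rng(0).normal(size=50)
        _, _, eta = simulate_legacy_scale(theta, 1.0, 4, seed=3)
        assert np.allclose(eta, theta)

    def test_best_category_scores_100(self):
        # category 0 ("never a problem") maps to item score 100
        theta = np.full(20, -10.0)  # forces category 0 on most items
        items, scores, _ = simulate_legacy_scale(theta, 1.0, 4, seed=3)
        best = items.to_numpy() == 0
        assert best.mean() > 0.9
        assert scores[items.to_numpy().sum(axis=1) == 0].min() == pytest.approx(100.0)

    def test_target_correlation_recovered(self):
        theta = np.random.default_rng(1).normal(size=5000)
        _, _, eta = simulate_legacy_scale(theta, 0.7, 5, seed=4)
        r = np.corrcoef(theta, eta)[0, 1]
        assert 0.67 <= r <= 0.73

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            simulate_legacy_scale(np.zeros(5), 1.5, 4, seed=0)


class TestReferenceSample:
    def _pool(self, n, p_female, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "person_id": np.arange(n),
                "sex": np.where(rng.random(n) < p_female, "female", "male"),
            }
        )

    def test_matching_pool_zero_flags(self):
        pool = pd.DataFrame(
            {"person_id": range(100), "sex": ["male", "female"] * 50}
        )
        sub, report = draw_reference_sample(
            pool, {"sex": {"male": 0.5, "female": 0.5}}, 0.025, n_target=80, seed=1
        )
        assert len(sub) == 80
        assert not report.flagged.any()

    def test_missing_stratum_flagged(self):
        pool = pd.DataFrame({"person_id": range(50), "sex": ["male"] * 50})
        sub, report = draw_reference_sample(
            pool, {"sex": {"male": 0.5, "female": 0.5}}, 0.025, n_target=30, seed=1
        )
        assert report.loc[report.covariate == "sex", "flagged"].item()

    def test_skewed_pool_balanced_when_feasible(self):
        # 80/20 pool, 50/50 target: 200-person subsample needs 100 of the
        # minority; pool of 1000 has ~200, so the margins are feasible
        pool = self._pool(1000, 0.2, seed=5)
        sub, report = draw_reference_sample(
            pool, {"sex": {"male": 0.5, "female": 0.5}}, 0.025, n_target=200, seed=2
        )
        prop = (sub.sex == "female").mean()
        assert 0.475 <= prop <= 0.525
        assert not report.flagged.any()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            draw_reference_sample(pd.DataFrame(), {"sex": {"m": 1.0}}, 0.025)
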