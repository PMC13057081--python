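"""Reliability/efficiency summaries, construct validity, reference tables."""

import numpy as np
import pandas as pd
import pytest

from promkit import (
    GradedResponseModel,
    construct_validity,
    efficiency,
    marginal_reliabilities,
    reference_values,
    relative_efficiency,
    reliability_summary,
    score_table,
    version_crosswalk,
)
from promkit.synthetic import (
    BankSpec,
    PopulationSpec,
    generate_item_bank,
    simulate_responses,
    simulate_thetas,
)


def make_scores(se_values, raw=None):
    se = np.asarray(se_values, dtype=float)
    return pd.DataFrame(
        {
            "person_id": np.arange(se.size),
            "theta_hat": np.zeros(se.size),
            "se_theta": se,
            "t_score": np.full(se.size, 50.0),
            "raw_sum": raw if raw is not None else np.arange(se.size),
        }
    )


class TestReliabilitySummary:
    def test_all_reliable(self):
        out = reliability_summary(make_scores([0.2] * 10), n_items=8)
        assert out.pct_reliable == 100.0

    def test_none_reliable(self):
        out = reliability_summary(make_scores([0.5] * 10), n_items=8)
        assert out.pct_reliable == 0.0

    def test_ceiling_exclusion_improves_reliability(self):
        """Ceiling-skewed sample: excluding best-possible raw scores raises
        the share of reliable measurements (the fatigue/mobility pattern)."""
        bank = generate_item_bank(BankSpec(10, name="r"), seed=61)
        pop = PopulationSpec(n_persons=2000, ceiling_mass=0.3, ceiling_direction="symptom")
        theta = simulate_thetas(pop, seed=62)["theta"].to_numpy()
        resp = simulate_responses(bank, theta, seed=63)
        scores = score_table(resp.data, bank)
        total = reliability_summary(scores, 10, "symptom", exclude_ceiling=False)
        no_ceiling = reliability_summary(scores, 10, "symptom", exclude_ceiling=True, max_raw=40)
        assert no_ceiling.pct_reliable > total.pct_reliable
        assert no_ceiling.mean_se < total.mean_se
        assert no_ceiling.n_persons < total.n_persons

    def test_ceiling_sample_empirical_below_theoretical(self):
        """Ceiling data: empirical marginal reliability lags the theoretical
        coefficient (the mobility signature)."""
        bank = generate_item_bank(
            BankSpec(10, threshold_span=(-3.0, 0.0), direction="function", name="m"),
            seed=64,
        )
        pop = PopulationSpec(n_persons=2000, ceiling_mass=0.4, ceiling_direction="function")
        theta = simulate_thetas(pop, seed=65)["theta"].to_numpy()
        resp = simulate_responses(bank, theta, seed=66)
        scores = score_table(resp.data, bank)
        rho_t, rho_e = marginal_reliabilities(bank, scores)
        assert rho_e < rho_t - 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reliability_summary(make_scores([]), 5)


class TestEfficiency:
    def test_quoted_formula(self):
        assert efficiency(0.32, 8) == pytest.approx((1 - 0.32**2) / 8)
        assert efficiency(0.32, 8) == pytest.approx(0.1122, abs=1e-4)

    def test_se_one_gives_zero(self):
        assert efficiency(1.0, 5) == 0.0

    def test_halving_items_doubles(self):
        assert efficiency(0.32, 4) == pytest.approx(2 * efficiency(0.32, 8))
        assert efficiency(0.32, 4) == pytest.approx(0.2244, abs=1e-4)

    def test_se_above_one_floored(self):
        assert efficiency(1.2, 5) == 0.0


class TestRelativeEfficiency:
    def test_self_comparison_identity(self):
        rng = np.random.default_rng(0)
        se = rng.uniform(0.2, 0.6, size=500)
        comp = relative_efficiency(se, 10, se, 10, n_boot=1000, seed=3)
        assert comp.ratio == pytest.approx(1.0)
        assert comp.ci_low <= 1.0 <= comp.ci_high

    def test_directional_cat_advantage(self):
        rng = np.random.default_rng(1)
        se_bank = rng.uniform(0.2, 0.35, size=500)
        se_cat = np.clip(se_bank + rng.normal(0, 0.02, 500), 0.05, None)
        comp = relative_efficiency(se_bank, 15, se_cat, 6, n_boot=1000, seed=4)
        assert comp.ratio > 1
        assert comp.ci_low > 1

    def test_bootstrap_ci_coverage(self):
        """Percentile CI covers the true ratio about 95% of the time."""
        rng = np.random.default_rng(2)
        n, reps, covered = 300, 100, 0
        for _ in range(reps):
            se_a = rng.uniform(0.25, 0.45, size=n)
            se_b = rng.uniform(0.25, 0.45, size=n)
            true_ratio = (1 - np.mean(np.square(np.linspace(0.25, 0.45, 10**5)))) / (
                1 - np.mean(np.square(np.linspace(0.25, 0.45, 10**5)))
            )  # population means equal: true ratio 1
            comp = relative_efficiency(
                se_a, 10, se_b, 10, n_boot=200, seed=int(rng.integers(2**31))
            )
            covered += comp.ci_low <= true_ratio <= comp.ci_high
        assert 0.91 <= covered / reps <= 0.99

    def test_mismatched_persons_rejected(self):
        with pytest.raises(ValueError):
            relative_efficiency(np.full(5, 0.3), 5, np.full(6, 0.3), 5)


class TestConstructValidity:
    def test_met_and_not_met(self):
        rng = np.random.default_rng(3)
        n = 529
        x = rng.normal(size=n)
        strong = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=n)
        weak = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(size=n)
        out = construct_validity(
            {"m": x},
            {"strong": strong, "weak": weak},
            [
                {"measure": "m", "legacy": "strong", "expected_threshold": 0.50},
                {"measure": "m", "legacy": "weak", "expected_threshold": 0.70},
            ],
        )
        assert out.met.tolist() == [True, False]
        assert out.note.tolist() == ["", "mismatch"]

    def test_exact_linear_transform(self):
        t = np.linspace(30, 70, 100)
        out = construct_validity(
            {"m": t},
            {"legacy": 100 - 0.8 * t},
            [{"measure": "m", "legacy": "legacy", "expected_threshold": 0.99}],
        )
        assert out.observed_r[0] == pytest.approx(1.0)
        assert bool(out.met[0])

    def test_zero_variance_flagged(self):
        out = construct_validity(
            {"m": np.ones(10)},
            {"legacy": np.arange(10.0)},
            [{"measure": "m", "legacy": "legacy", "expected_threshold": 0.5}],
        )
        assert out.note[0] == "zero variance"
        assert not bool(out.met[0])


class TestReferenceValues:
    def test_constant_sample(self):
        scores = make_scores([0.3] * 20)
        covs = pd.DataFrame({"child_sex": ["m", "f"] * 10})
        out = reference_values(scores, covs, {"child_sex": "child_sex"})
        total = out[out.grouping == "total"].iloc[0]
        assert total["mean"] == 50.0 and total["sd"] == 0.0

    def test_subgroup_means_recombine(self):
        rng = np.random.default_rng(4)
        scores = make_scores(rng.uniform(0.2, 0.4, 50))
        scores["t_score"] = rng.normal(50, 10, 50)
        covs = pd.DataFrame({"sex": rng.choice(["m", "f"], 50)})
        out = reference_values(scores, covs, {"sex": "sex"})
        total = out[out.grouping == "total"].iloc[0]
        subs = out[out.grouping == "sex"]
        weighted = (subs["mean"] * subs["n"]).sum() / subs["n"].sum()
        assert weighted == pytest.approx(total["mean"])
        assert subs["n"].sum() == total["n"]

    def test_own_calibration_anchors_to_50(self):
        bank = generate_item_bank(BankSpec(10, name="a"), seed=71)
        rng = np.random.default_rng(72)
        resp = simulate_responses(bank, rng.normal(size=10_000), seed=73)
        scores = score_table(resp.data, bank)
        out = reference_values(scores, pd.DataFrame(index=range(10_000)))
        assert out.iloc[0]["mean"] == pytest.approx(50.0, abs=0.3)


@pytest.fixture(scope="module")
def crosswalk_data():
    bank = generate_item_bank(BankSpec(10, name="v3"), seed=81)
    rng = np.random.default_rng(82)
    resp = simulate_responses(bank, rng.normal(size=400), seed=83)
    return bank, resp


class TestVersionCrosswalk:

    def test_identical_anchors_identical_scores(self, crosswalk_data):
        bank, resp = crosswalk_data
        items = list(range(10))
        a, b, comp = version_crosswalk(resp.data, bank, items, bank, items)
        assert np.array_equal(a.theta_hat, b.theta_hat)
        assert not comp["provisional_b"]

    def test_subset_cannot_reduce_se(self, crosswalk_data):
        bank, resp = crosswalk_data
        a, b, comp = version_crosswalk(
            resp.data, bank, list(range(10)), bank.subset(range(7)), list(range(7))
        )
        assert comp["mean_se_theta_b"] >= comp["mean_se_theta_a"]
        assert comp["provisional_b"]
        assert comp["mean_se_t_units_b"] == pytest.approx(10 * comp["mean_se_theta_b"])

    def test_different_anchors_shift_t_scores(self, crosswalk_data):
        """Distinct parameter sets re-score identical responses differently."""
        bank, resp = crosswalk_data
        from promkit import ItemParameters

        shifted = ItemParameters(
            bank.alphas, [b + 0.4 for b in bank.betas], bank.item_names
        )
        items = list(range(10))
        a, b, comp = version_crosswalk(resp.data, bank, items, shifted, items)
        assert comp["mean_t_b"] > comp["mean_t_a"] + 1.0

    def test_empty_subset_rejected(self, crosswalk_data):
        bank, resp = crosswalk_data
        with pytest.raises(ValueError):
            version_crosswalk(resp.data, bank, [], bank, [])
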