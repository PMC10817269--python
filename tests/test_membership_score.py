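"""Membership normalisation, weights, D values and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtrank.membership_score import (
    Weights,
    d_value,
    evaluate_from_ci,
    membership,
    rank_treatments,
    run_full_evaluation,
    weights,
)
from droughtrank.synthetic_data import SimulationConfig, simulate_trait_table


class TestMembership:
    def test_published_extremes(self, table2_ci):
        mu = membership(table2_ci)
        assert mu.loc["Jacg121", "mu1"] == 1.0  # column max
        assert mu.loc["Jacg81", "mu2"] == 0.0  # column min
        assert mu.loc["CK", "mu1"] == 0.0

    def test_published_interior_value(self, table2_ci):
        mu = membership(table2_ci)
        # (0.555 + 1.693) / (1.991 + 1.693)
        assert mu.loc["Jacg37", "mu1"] == pytest.approx(0.6102, abs=1e-4)

    def test_bounds_and_attainment(self, table2_ci):
        mu = membership(table2_ci)
        assert ((mu >= 0) & (mu <= 1)).all().all()
        assert (mu.min() == 0).all() and (mu.max() == 1).all()

    def test_degenerate_column_named(self):
        ci = pd.DataFrame({"CI1": [1.0, 2.0, 3.0], "CI2": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="CI2"):
            membership(ci)

    def test_affine_invariance(self, table2_ci):
        """A strictly increasing affine map of a CI column leaves mu (hence D)
        unchanged: min-max normalisation absorbs it."""
        shifted = table2_ci.copy()
        shifted["CI2"] = 3.5 * shifted["CI2"] + 11.0
        pd.testing.assert_frame_equal(membership(table2_ci), membership(shifted))


class TestWeights:
    def test_published_rates_recompute(self):
        w = weights([68.426, 12.359, 7.722])
        assert w.values[1] == pytest.approx(0.1396, abs=5e-5)
        assert round(w.values[1], 3) == 0.140
        assert w.values.sum() == pytest.approx(1.0)

    def test_single_and_equal_rates(self):
        assert weights([42.0]).values.tolist() == [1.0]
        assert np.allclose(weights([10, 10, 10]).values, 1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weights([])

    def test_supplied_sum_window(self):
        Weights(values=np.array([0.770, 0.140, 0.09]), source="supplied")  # ok
        with pytest.raises(ValueError, match="outside"):
            Weights(values=np.array([0.5, 0.2]), source="supplied")


class TestDValue:
    def test_published_d_column(self, table2_ci, table2_weights, table2_published):
        mu = membership(table2_ci)
        score = d_value(mu, table2_weights)
        for treatment, expected in table2_published["D"].items():
            assert score.d[treatment] == pytest.approx(expected, abs=1e-3)

    def test_published_ranking(self, table2_ci, table2_weights, table2_published):
        score = d_value(membership(table2_ci), table2_weights)
        assert score.rank.tolist() == table2_published["rank"].tolist()
        assert score.rank["Jacg121"] == 1 and score.rank["CK"] == 9

    def test_upper_bound(self):
        mu = pd.DataFrame(np.ones((4, 3)), columns=["mu1", "mu2", "mu3"])
        score = d_value(mu, weights([50, 30, 20]))
        assert np.allclose(score.d, 1.0)

    def test_dimension_mismatch(self, table2_ci):
        with pytest.raises(ValueError, match="mismatch"):
            d_value(membership(table2_ci), weights([60, 40]))

    def test_tied_scores_share_smaller_rank(self):
        mu = pd.DataFrame(
            {"mu1": [1.0, 1.0, 0.0]}, index=["a", "b", "c"]
        )
        score = d_value(mu, weights([100.0]))
        assert score.rank.tolist() == [1, 1, 3]

    def test_monotone_in_single_ci(self, table2_ci, table2_weights):
        """Raising one treatment's CI (within the column range) never lowers
        its D."""
        base = d_value(membership(table2_ci), table2_weights).d["Jacg37"]
        bumped = table2_ci.copy()
        bumped.loc["Jacg37", "CI1"] += 0.5  # still below the column max
        after = d_value(membership(bumped), table2_weights).d["Jacg37"]
        assert after >= base

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_d_bounded_for_random_ci(self, seed):
        rng = np.random.default_rng(seed)
        ci = pd.DataFrame(rng.normal(size=(6, 3)), columns=["CI1", "CI2", "CI3"])
        score = d_value(membership(ci), weights([50, 30, 20]))
        assert (score.d >= -1e-12).all() and (score.d <= 1 + 1e-12).all()


class TestFullEvaluation:
    def test_from_ci_report_reproduces_published_table(
        self, table2_ci, table2_weights, table2_published
    ):
        report = evaluate_from_ci(table2_ci, table2_weights)
        mu_cols = ["mu1", "mu2", "mu3"]
        assert np.allclose(
            report.mu[mu_cols], table2_published[mu_cols], atol=1e-3
        )
        assert np.allclose(report.score.d, table2_published["D"], atol=1e-3)
        assert report.score.rank.tolist() == table2_published["rank"].tolist()

    def test_zero_noise_recovers_planted_order(self):
        table, truth = simulate_trait_table(SimulationConfig(noise_sd=0.0, seed=3))
        report = run_full_evaluation(table, policy="kaiser")
        d = report.score.d
        recovered = d.sort_values(ascending=False).index.tolist()
        planted = truth.sort_values(ascending=False).index.tolist()
        assert recovered == planted

    def test_determinism(self):
        table, _ = simulate_trait_table(SimulationConfig(seed=5))
        r1 = run_full_evaluation(table, policy="fixed_k", k=3)
        r2 = run_full_evaluation(table, policy="fixed_k", k=3)
        pd.testing.assert_series_equal(r1.score.d, r2.score.d)
        pd.testing.assert_frame_equal(r1.summary(), r2.summary())

    def test_supplied_weights_path(self):
        table, _ = simulate_trait_table(SimulationConfig(seed=6))
        report = run_full_evaluation(
            table,
            policy="fixed_k",
            k=3,
            weight_source="supplied",
            supplied_weights=[0.8, 0.12, 0.08],
        )
        assert report.weights.source == "supplied"
        assert report.config["k"] == 3

    def test_rank_treatments_ordering(self, table2_ci, table2_weights):
        score = d_value(membership(table2_ci), table2_weights)
        ordered = rank_treatments(score)
        assert ordered.index[0] == "Jacg121"
        assert ordered.index[-1] == "CK"
        assert (np.diff(ordered["D"].to_numpy()) <= 1e-12).all()
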