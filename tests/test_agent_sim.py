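import math

import numpy as np
import pandas as pd
import pytest

from transinf.models import AgentState, update_item_values
from transinf.simulate import (
    learning_curves,
    pair_categories,
    simulate_agent,
    sweep_learning_rates,
    value_compression_index,
)


class TestSimulateAgent:
    def test_no_learning_keeps_chance_probabilities(self):
        res = simulate_agent(
            "exp2", "Q2", {"alpha_plus": 0.0, "alpha_minus": 0.0, "tau_item": 0.2}, 1
        )
        assert np.allclose(res.trials["cp_hi"], 0.5)
        assert np.allclose(res.q_final, 0.0)
        assert 0.4 < res.accuracy < 0.6

    def test_first_choice_is_random_guess(self):
        res = simulate_agent("exp1", "Q1", {"alpha": 0.1, "tau_item": 0.2}, 3)
        assert res.trials["cp_hi"].iloc[0] == 0.5

    def test_determinism_under_seed(self):
        kw = dict(alpha_plus=0.05, alpha_minus=0.0, eta=8.0, tau_item=0.04)
        a = simulate_agent("partial_uniform", "Q2*", kw, 11)
        b = simulate_agent("partial_uniform", "Q2*", kw, 11)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert np.array_equal(a.q_final, b.q_final)

    def test_engine_matches_scalar_reference_updates(self):
        """The vectorised engine replays the scalar model ops step for step."""
        res = simulate_agent(
            "partial_uniform",
            "Q2*",
            {"alpha_plus": 0.06, "alpha_minus": 0.01, "eta": 2.0, "tau_item": 0.1},
            7,
            record_q=True,
        )
        p = res.params
        state = AgentState(8)
        for t, row in res.trials.iterrows():
            if row.feedback_scheduled:
                w = int(row.outcome_winner)
                l = int(row.item_hi if w == row.item_lo else row.item_lo)
                update_item_values(state, w, l, p)
            assert np.allclose(res.q_traj[t], state.q_values, atol=1e-12)

    def test_plain_q_learns_nothing_about_intermediate_items(self):
        """Without difference weighting, partial feedback teaches only the
        extremes; intermediate items win and lose neighbour comparisons
        equally often, so their values stay near zero on average."""
        finals = []
        for seed in range(40):
            res = simulate_agent(
                "partial_uniform", "Q1", {"alpha": 0.05, "tau_item": 0.04}, seed
            )
            finals.append(res.q_final)
        mean_q = np.mean(finals, axis=0)
        sem_q = np.std(finals, axis=0, ddof=1) / math.sqrt(len(finals))
        assert mean_q[0] > 10 * sem_q[0]  # top item clearly positive
        assert mean_q[-1] < -10 * sem_q[-1]  # bottom item clearly negative
        assert np.all(np.abs(mean_q[2:6]) < 5 * sem_q[2:6])

    def test_difference_weighting_enables_transitive_inference(self):
        accs = []
        for seed in range(50):
            res = simulate_agent(
                "partial_uniform", "Q1*", {"alpha": 0.05, "eta": 8.0, "tau_item": 0.04}, seed
            )
            dist = res.trials.item_lo - res.trials.item_hi
            accs.append(res.trials.loc[dist > 1, "correct"].mean())
        mean, sem = np.mean(accs), np.std(accs, ddof=1) / math.sqrt(len(accs))
        assert mean - 0.5 > 5 * sem

    def test_choice_matrix_antisymmetric_with_nan_diagonal(self):
        res = simulate_agent("exp1", "Q1", {"alpha": 0.05, "tau_item": 0.2}, 5)
        M = res.choice_matrix()
        assert np.all(np.isnan(np.diag(M)))
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(M[off] + M.T[off], 1.0)


class TestDistanceEffects:
    @staticmethod
    def _accuracy_by_distance(model, params, n_agents=40):
        acc = np.zeros(7)
        cnt = np.zeros(7)
        for seed in range(n_agents):
            res = simulate_agent("exp2", model, params, seed)
            dist = (res.trials.item_lo - res.trials.item_hi).to_numpy()
            corr = res.trials["correct"].to_numpy()
            for d in range(1, 8):
                acc[d - 1] += corr[dist == d].sum()
                cnt[d - 1] += (dist == d).sum()
        return acc / cnt

    def test_item_learning_shows_positive_distance_effect(self):
        a = self._accuracy_by_distance(
            "Q1*", {"alpha": 0.05, "eta": 8.0, "tau_item": 0.04}
        )
        assert a[6] > a[1] + 0.05  # far pairs easier than near pairs

    def test_pair_inference_shows_inverse_distance_effect(self):
        a = self._accuracy_by_distance(
            "Pi", {"gamma": 0.5, "lambda_": 1.0, "tau_pair": 0.1}
        )
        assert a[0] > a[3] > a[6]  # accuracy decreases with rank distance

    def test_pair_memory_without_inference_is_chance_on_non_neighbours(self):
        a = self._accuracy_by_distance(
            "P", {"gamma": 0.5, "tau_pair": 0.1}, n_agents=20
        )
        assert a[0] > 0.7  # neighbours learned
        assert np.all(np.abs(a[1:] - 0.5) < 0.03)


class TestSweep:
    def test_zero_learning_cell_is_chance(self):
        grid = np.array([0.0, 0.05])
        res = sweep_learning_rates(
            "partial_uniform",
            "Q2*",
            {"eta": 8.0, "tau_item": 0.04},
            grid=grid,
            n_replications=10,
            seed=0,
        )
        assert res.performance[0, 0] == pytest.approx(0.5, abs=0.04)
        assert res.performance.shape == (2, 2)

    def test_symmetric_model_sweeps_diagonal_only(self):
        grid = np.array([0.0, 0.02, 0.05])
        res = sweep_learning_rates(
            "exp1", "Q1", {"tau_item": 0.2}, grid=grid, n_replications=5, seed=1
        )
        assert np.isnan(res.performance[0, 1])
        assert not np.isnan(res.performance[1, 1])

    def test_winner_loser_duality_under_partial_feedback(self):
        """Selective winner-updating and selective loser-updating are
        statistically equivalent policies."""
        grid = np.array([0.0, 0.05])
        res = sweep_learning_rates(
            "partial_uniform",
            "Q2*",
            {"eta": 8.0, "tau_item": 0.04},
            grid=grid,
            n_replications=60,
            seed=2,
        )
        winner_only = res.performance[1, 0]
        loser_only = res.performance[0, 1]
        assert winner_only > 0.7 and loser_only > 0.7
        assert abs(winner_only - loser_only) < 0.03

    def test_replications_required(self):
        with pytest.raises(ValueError):
            sweep_learning_rates(
                "exp1", "Q1", {"tau_item": 0.2}, grid=np.array([0.0]), n_replications=0
            )


class TestLearningCurves:
    def test_categories_partition_non_neighbours_equally(self):
        cats = pair_categories(8)
        non = [c for c in cats.values() if c != "neighbour"]
        assert len(non) == 21
        assert sorted(non).count("low") == 7
        assert sorted(non).count("medium") == 7
        assert sorted(non).count("high") == 7
        assert cats[(1, 3)] == "high" and cats[(6, 8)] == "low"

    def test_window_equal_to_session_is_overall_mean(self):
        res = simulate_agent(
            "exp2", "Q2*", {"alpha_plus": 0.05, "alpha_minus": 0.0, "eta": 8.0, "tau_item": 0.04}, 3
        )
        T = len(res.trials)
        curves = learning_curves([res], window=T, categories=["low"])
        assert len(curves) == 1
        dist = res.trials.item_lo - res.trials.item_hi
        cats = pair_categories(8)
        mask = [
            cats[(h, l)] == "low"
            for h, l in zip(res.trials.item_hi, res.trials.item_lo)
        ]
        assert curves.accuracy.iloc[0] == pytest.approx(
            res.trials.loc[mask, "correct"].mean()
        )

    def test_empty_category_flagged_not_dropped(self):
        res = simulate_agent("exp2", "Q1", {"alpha": 0.05, "tau_item": 0.2}, 1)
        df = res.trials.head(3).copy()  # tiny slice may miss categories
        with pytest.warns(UserWarning, match="absent"):
            curves = learning_curves([df], window=2, categories=["low", "high"])
        assert set(curves.category) == {"low", "high"}

    def test_invalid_window_rejected(self):
        res = simulate_agent("exp2", "Q1", {"alpha": 0.05, "tau_item": 0.2}, 1)
        with pytest.raises(ValueError):
            learning_curves([res], window=10**6)


class TestCompressionIndex:
    def test_linear_profile_is_zero(self):
        assert value_compression_index(np.linspace(1, -1, 8)) == pytest.approx(0.0)

    def test_concave_profile_is_negative(self):
        q = np.log(np.arange(8, 0, -1) + 1.0)
        assert value_compression_index(q) < 0

    def test_convex_profile_is_positive(self):
        q = np.exp(np.linspace(1, 0, 8))  # larger gaps among top items
        assert value_compression_index(q) > 0

    def test_rejects_non_finite_and_short_input(self):
        with pytest.raises(ValueError):
            value_compression_index([1.0, np.nan, 0.0, -1.0])
        with pytest.raises(ValueError):
            value_compression_index([1.0, 0.0, -1.0])
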