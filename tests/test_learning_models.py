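import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transinf.models import (
    DEFAULT_BOUNDS,
    FAMILY8,
    MODELS,
    AgentParams,
    AgentState,
    arbitrate,
    choice_prob_item,
    choice_prob_pair,
    get_model,
    infer_pair_preference,
    resolve_attribution,
    update_item_values,
    update_pair_memory,
)


def params(**kw):
    base = dict(alpha_plus=0.1, alpha_minus=0.1, tau_item=0.2, eta=0.0)
    base.update(kw)
    return AgentParams(**base)


class TestItemUpdating:
    def test_delta_rule_from_zero_state(self):
        s = AgentState(3)
        update_item_values(s, 1, 2, params())
        assert s.q_values[0] == pytest.approx(0.1)
        assert s.q_values[1] == pytest.approx(-0.1)
        assert s.q_values[2] == 0.0

    def test_targets_are_fixed_points(self):
        s = AgentState(3)
        s.q_values[:] = [1.0, -1.0, 0.0]
        update_item_values(s, 1, 2, params(alpha_plus=0.17, alpha_minus=0.05))
        assert s.q_values[0] == 1.0
        assert s.q_values[1] == -1.0

    def test_difference_weighted_update(self):
        # d = eta*(Qw - Ql) = 1; winner target shrinks to 1 - d = 0
        s = AgentState(3)
        s.q_values[:] = [0.5, -0.5, 0.0]
        update_item_values(s, 1, 2, params(eta=1.0, alpha_plus=0.1, alpha_minus=0.0))
        assert s.q_values[0] == pytest.approx(0.45)
        assert s.q_values[1] == -0.5

    def test_unknown_item_rejected(self):
        with pytest.raises(ValueError):
            update_item_values(AgentState(3), 1, 4, params())
        with pytest.raises(ValueError):
            update_item_values(AgentState(3), 2, 2, params())


class TestChoiceRules:
    def test_item_logistic_values(self):
        s = AgentState(3)
        assert choice_prob_item(s, 1, 2, 0.2) == 0.5
        s.q_values[:] = [0.2, 0.0, 0.0]
        assert choice_prob_item(s, 1, 2, 0.2) == pytest.approx(
            1 / (1 + math.exp(-1)), abs=1e-12
        )
        # near-zero temperature approaches a step function
        assert choice_prob_item(s, 1, 2, 1e-6) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            choice_prob_item(s, 1, 2, 0.0)

    def test_item_choice_antisymmetric(self):
        s = AgentState(4)
        s.q_values[:] = [0.3, -0.2, 0.1, 0.0]
        for i, j in [(1, 2), (2, 3), (1, 4)]:
            assert choice_prob_item(s, i, j, 0.1) + choice_prob_item(
                s, j, i, 0.1
            ) == pytest.approx(1.0, abs=1e-12)

    def test_pair_logistic_centred(self):
        assert choice_prob_pair(0.5, 0.1) == 0.5
        assert choice_prob_pair(0.7, 0.1) == pytest.approx(
            1 / (1 + math.exp(-2)), abs=1e-12
        )
        for p in (0.0, 0.21, 0.9):
            assert choice_prob_pair(p, 0.1) + choice_prob_pair(
                1 - p, 0.1
            ) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            choice_prob_pair(0.5, 0.0)
        with pytest.raises(ValueError):
            choice_prob_pair(1.2, 0.1)


class TestPairMemory:
    def test_truthful_updates_upper_count(self):
        s = AgentState(8)
        update_pair_memory(s, (1, 2), True, 1.0)
        assert (s.pair_u[0], s.pair_l[0]) == (2.0, 1.0)
        assert s.pair_preference(1) == pytest.approx(2 / 3)

    def test_untruthful_updates_lower_count(self):
        s = AgentState(8)
        update_pair_memory(s, (3, 4), False, 0.5)
        assert (s.pair_u[2], s.pair_l[2]) == (1.0, 1.5)

    def test_zero_gamma_never_learns(self):
        s = AgentState(8)
        for _ in range(10):
            update_pair_memory(s, (1, 2), True, 0.0)
        assert s.pair_preference(1) == 0.5

    def test_balanced_evidence_is_indifferent(self):
        s = AgentState(8)
        for _ in range(4):
            update_pair_memory(s, (5, 6), True, 0.3)
            update_pair_memory(s, (5, 6), False, 0.3)
        assert s.pair_preference(5) == pytest.approx(0.5)

    def test_count_conservation(self):
        s = AgentState(8)
        for k in range(7):
            update_pair_memory(s, (2, 3), k % 2 == 0, 0.25)
        assert s.pair_u[1] + s.pair_l[1] == pytest.approx(2.0 + 7 * 0.25)

    def test_non_neighbour_pair_rejected(self):
        with pytest.raises(ValueError):
            update_pair_memory(AgentState(8), (1, 3), True, 1.0)


class TestPairInference:
    def test_chained_average_at_lambda_zero(self):
        s = AgentState(8)
        s.pair_u[:] = 7.0
        s.pair_l[:] = 3.0  # every neighbour preference 0.7
        assert infer_pair_preference(s, 1, 3, 0.0) == pytest.approx(0.7)
        assert infer_pair_preference(s, 1, 8, 0.0) == pytest.approx(0.7)

    def test_neighbour_distance_ignores_lambda(self):
        s = AgentState(8)
        s.pair_u[0] = 4.0
        for lam in (0.0, 1.0, 50.0, 100.0):
            assert infer_pair_preference(s, 1, 2, lam) == pytest.approx(0.8)

    def test_large_lambda_collapses_to_indifference(self):
        s = AgentState(8)
        s.pair_u[:] = 99.0
        for dist_pair in [(1, 3), (2, 6), (1, 8)]:
            assert infer_pair_preference(s, *dist_pair, 100.0) == pytest.approx(
                0.5, abs=1e-15
            )

    def test_preference_shrinks_with_distance_for_positive_lambda(self):
        s = AgentState(8)
        s.pair_u[:] = 7.0
        s.pair_l[:] = 3.0
        prefs = [infer_pair_preference(s, 1, 1 + d, 1.0) for d in range(1, 8)]
        assert all(a > b for a, b in zip(prefs, prefs[1:]))
        assert all(p > 0.5 for p in prefs)


class TestArbitration:
    @pytest.mark.parametrize(
        "cpi,cpp,expected,source",
        [
            (0.8, 0.6, 0.8, "item"),
            (0.5, 0.9, 0.9, "pair"),
            (0.3, 0.6, 0.3, "item"),  # |0.3-0.5| > |0.6-0.5|, sign irrelevant
            (0.5, 0.5, 0.5, "item"),  # tie -> item level
        ],
    )
    def test_stronger_preference_wins(self, cpi, cpp, expected, source):
        assert arbitrate(cpi, cpp) == (expected, source)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            arbitrate(1.3, 0.5)


class TestAttribution:
    def test_correct_choice_identical_in_both_modes(self):
        assert resolve_attribution(1, 2, 1, 2, "winner_loser") == (1, 2)
        assert resolve_attribution(1, 2, 1, 2, "chosen_unchosen") == (1, 2)

    def test_error_choice_swaps_rates_in_chosen_mode(self):
        # agent chose the loser: alpha_plus follows the chosen item
        assert resolve_attribution(1, 2, 2, 1, "winner_loser") == (1, 2)
        assert resolve_attribution(1, 2, 2, 1, "chosen_unchosen") == (2, 1)

    def test_inconsistent_items_rejected(self):
        with pytest.raises(ValueError):
            resolve_attribution(1, 2, 1, 3, "winner_loser")


class TestModelSpace:
    def test_registry_structure(self):
        assert set(FAMILY8) <= set(MODELS)
        for spec in MODELS.values():
            p = spec.make_params([np.mean(b) for b in spec.bounds()])
            assert isinstance(p, AgentParams)

    def test_every_spec_restricts_the_full_model(self):
        full = MODELS["Q2*+Pi"]
        full_free = set(full.free_params)
        for spec in MODELS.values():
            free = {
                "alpha_plus" if f == "alpha" else f for f in spec.free_params
            }
            assert free <= full_free | {"alpha_minus"}

    def test_symmetric_specs_tie_learning_rates(self):
        p = MODELS["Q1"].make_params({"alpha": 0.07, "tau_item": 0.1})
        assert p.alpha_plus == p.alpha_minus == 0.07

    def test_pure_q_models_fix_gamma_zero(self):
        for name in ("Q1", "Q2", "Q1*", "Q2*"):
            assert MODELS[name].fixed_params["gamma"] == 0.0
            assert not MODELS[name].uses_pair

    def test_p_variants_fix_lambda_sentinel(self):
        assert MODELS["Q2*+P"].fixed_params["lambda_"] == 100.0
        assert "lambda_" in MODELS["Q2*+Pi"].free_params

    def test_unknown_model_and_param_errors(self):
        with pytest.raises(ValueError):
            get_model("Q9")
        with pytest.raises(ValueError):
            MODELS["Q1"].make_params({"gamma": 0.1})


@given(
    st.floats(0.0, 0.2),
    st.floats(0.0, 0.2),
    st.floats(0.0, 10.0),
    st.integers(0, 2**31 - 1),
)
@settings(max_examples=60, deadline=None)
def test_q_values_stay_bounded_in_stable_regime(ap, am, eta, seed):
    """Closed-loop updating from flat priors never escapes |Q| <= 2.

    Holds in the linearly stable regime alpha * (1 + 2 eta) <= 2; outside
    it the difference-weighted map is an expansion and values diverge by
    construction (the simulation sweeps stay well inside the stable
    region).
    """
    if max(ap, am) * (1.0 + 2.0 * eta) > 2.0:
        return
    rng = np.random.default_rng(seed)
    s = AgentState(4)
    p = params(alpha_plus=ap, alpha_minus=am, eta=eta)
    for _ in range(120):
        i = int(rng.integers(1, 4))
        update_item_values(s, i, i + 1, p)
    assert np.all(np.abs(s.q_values) <= 2.0)
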