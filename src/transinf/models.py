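"""The learning-model family for pairwise relational choice.

Two learning systems are modelled, separately and in combination.

**Item-level Q-learning.** Each item i carries an estimated value Q(i),
initialised at 0. After feedback declaring item i the winner over item j,
a delta rule updates both items towards signed targets:

    d      = eta * (Q(i) - Q(j))                 (difference weighting)
    Q(i) <- Q(i) + alpha_plus  * ( 1 - d - Q(i))
    Q(j) <- Q(j) + alpha_minus * (-1 + d - Q(j))

With ``eta = 0`` this is plain Rescorla-Wagner-style updating towards
+/-1; with ``eta > 0`` an outcome consistent with the current value
difference induces weaker updates, which lets value differences propagate
along the rank order and supports transitive inference. Tying
``alpha_plus = alpha_minus`` gives the symmetric variants. Choices follow
a logistic rule on the value difference with temperature ``tau_item``.

**Pair-level beta memory.** Each neighbouring pair n keeps beta counts
(U_n, L_n), initialised at (1, 1). Truthful feedback increments U_n by
``gamma``, untruthful feedback increments L_n; the learned preference for
the higher-ranked member is the beta mean p_n = U_n / (U_n + L_n).
Preferences for non-neighbours are inferred by chaining the linking
neighbour preferences, discounted by rank distance:

    p_{i>j} = sum_n (p_n - 0.5) / |i-j|**(lambda_ + 1) + 0.5

``lambda_ = 0`` is lossless averaging (perfect chaining); as ``lambda_``
grows, inferred preferences shrink to indifference. Pair-level choices
are logistic in the preference's deviation from 0.5 with temperature
``tau_pair``.

**Arbitration.** On each trial the response is driven by whichever
system currently holds the stronger preference, i.e. the larger
|CP - 0.5|; ties go to the item-level system. This implements a mixture
of the two learners without extra parameters.

All named model variants are restrictions of the most flexible model
(asymmetric, difference-weighted item learning plus inferential pair
memory); see :data:`MODELS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgentParams",
    "AgentState",
    "ModelSpec",
    "MODELS",
    "FAMILY8",
    "get_model",
    "DEFAULT_BOUNDS",
    "NEGATIVE_ALPHA_BOUNDS",
    "LAMBDA_SENTINEL",
    "update_item_values",
    "choice_prob_item",
    "update_pair_memory",
    "infer_pair_preference",
    "choice_prob_pair",
    "arbitrate",
    "resolve_attribution",
]

#: Fitting bounds (lower, upper) per parameter.
DEFAULT_BOUNDS = {
    "alpha": (0.0, 0.2),
    "alpha_plus": (0.0, 0.2),
    "alpha_minus": (0.0, 0.2),
    "eta": (0.0, 10.0),
    "tau_item": (0.01, 1.0),
    "gamma": (0.0, 1.0),
    "lambda_": (0.0, 100.0),
    "tau_pair": (0.01, 1.0),
}
# tau bounds are nominally (0, 1]; 0.01 is a numerical floor keeping the
# logistic finite during optimisation.

#: Widened learning-rate bounds for the negative-rate fitting mode.
NEGATIVE_ALPHA_BOUNDS = (-0.2, 0.2)

#: lambda_ value at which chained inference is effectively disabled
#: (pure pair memory, "P" variants): 1/d**(sentinel+1) underflows to 0
#: for any rank distance >= 2.
LAMBDA_SENTINEL = 100.0


@dataclass(frozen=True)
class AgentParams:
    """Full parameter set of one agent.

    ``attribution`` selects which items the two learning rates apply to:
    ``"winner_loser"`` (default) applies alpha_plus to the feedback-
    endorsed winner; ``"chosen_unchosen"`` applies alpha_plus to the item
    the agent chose, while the update *targets* (+1-like for the winner,
    -1-like for the loser) still follow the feedback.
    """

    alpha_plus: float
    alpha_minus: float
    tau_item: float
    eta: float = 0.0
    gamma: float = 0.0
    lambda_: float = LAMBDA_SENTINEL
    tau_pair: float = 0.1
    attribution: str = "winner_loser"

    def __post_init__(self):
        if self.attribution not in ("winner_loser", "chosen_unchosen"):
            raise ValueError(f"unknown attribution mode {self.attribution!r}")
        if self.tau_item <= 0:
            raise ValueError("tau_item must be positive")
        if self.tau_pair <= 0:
            raise ValueError("tau_pair must be positive")

    def as_dict(self) -> dict:
        return {
            "alpha_plus": self.alpha_plus,
            "alpha_minus": self.alpha_minus,
            "eta": self.eta,
            "tau_item": self.tau_item,
            "gamma": self.gamma,
            "lambda_": self.lambda_,
            "tau_pair": self.tau_pair,
        }


@dataclass
class AgentState:
    """Momentary learner state: item values and neighbour-pair counts.

    ``q_values[i-1]`` is the value estimate for item i; ``pair_u[n-1]``
    and ``pair_l[n-1]`` are the beta counts of neighbour pair n (items
    n, n+1). Flat priors: all Q = 0, all (U, L) = (1, 1), so every
    initial preference is 0.5 and the first choice is a coin flip.
    """

    n_items: int
    q_values: np.ndarray = field(default=None)
    pair_u: np.ndarray = field(default=None)
    pair_l: np.ndarray = field(default=None)
    trial_clock: int = 0

    def __post_init__(self):
        if self.q_values is None:
            self.q_values = np.zeros(self.n_items)
        if self.pair_u is None:
            self.pair_u = np.ones(self.n_items - 1)
        if self.pair_l is None:
            self.pair_l = np.ones(self.n_items - 1)

    def _check_item(self, i: int):
        if not 1 <= i <= self.n_items:
            raise ValueError(f"unknown item id {i} (1..{self.n_items})")

    def pair_preference(self, n: int) -> float:
        """Beta-mean preference of neighbour pair n for its higher member."""
        return float(self.pair_u[n - 1] / (self.pair_u[n - 1] + self.pair_l[n - 1]))

    def copy(self) -> "AgentState":
        return AgentState(
            self.n_items,
            self.q_values.copy(),
            self.pair_u.copy(),
            self.pair_l.copy(),
            self.trial_clock,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def update_item_values(
    state: AgentState, winner: int, loser: int, params: AgentParams
) -> AgentState:
    """Apply the (difference-weighted) delta rule after one feedback event.

    Mutates and returns ``state``. ``winner``/``loser`` are the items as
    endorsed by feedback; learning-rate attribution has already been
    resolved into ``params.alpha_plus`` applying to the winner update and
    ``params.alpha_minus`` to the loser update (see
    :func:`resolve_attribution` for the chosen/unchosen variant).
    """
    state._check_item(winner)
    state._check_item(loser)
    if winner == loser:
        raise ValueError("winner and loser must differ")
    q = state.q_values
    d = params.eta * (q[winner - 1] - q[loser - 1])
    q_w, q_l = q[winner - 1], q[loser - 1]
    q[winner - 1] = q_w + params.alpha_plus * (1.0 - d - q_w)
    q[loser - 1] = q_l + params.alpha_minus * (-1.0 + d - q_l)
    return state


def choice_prob_item(state: AgentState, i: int, j: int, tau_item: float) -> float:
    """Logistic probability of choosing item i over j from Q-values."""
    if tau_item <= 0:
        raise ValueError("tau_item must be positive")
    state._check_item(i)
    state._check_item(j)
    dq = state.q_values[i - 1] - state.q_values[j - 1]
    return float(1.0 / (1.0 + math.exp(-dq / tau_item)))


def update_pair_memory(
    state: AgentState, pair: tuple, truthful: bool, gamma: float
) -> AgentState:
    """Increment the beta counts of one neighbour pair after feedback.

    Truthful feedback (winner = truly higher member) raises U, untruthful
    feedback raises L, each by ``gamma``. Only neighbour pairs carry a
    direct feedback signal; calling this on a non-neighbour pair is a
    contract violation.
    """
    a, b = min(pair), max(pair)
    state._check_item(a)
    state._check_item(b)
    if b - a != 1:
        raise ValueError(f"pair {pair} is not a neighbour pair")
    if truthful:
        state.pair_u[a - 1] += gamma
    else:
        state.pair_l[a - 1] += gamma
    return state


def infer_pair_preference(state: AgentState, i: int, j: int, lambda_: float) -> float:
    """Preference p_{i>j} for the higher-ranked of items i and j.

    For neighbours this is the stored beta-mean preference; for more
    distant pairs the linking neighbour preferences are chained and
    discounted by ``|i-j|**(lambda_+1)``. Returns the preference for the
    *higher-ranked* member of the pair (values > 0.5 favour it).
    """
    a, b = min(i, j), max(i, j)
    state._check_item(a)
    state._check_item(b)
    if a == b:
        raise ValueError("items must differ")
    dist = b - a
    p = state.pair_u[a - 1 : b - 1] / (
        state.pair_u[a - 1 : b - 1] + state.pair_l[a - 1 : b - 1]
    )
    return float(np.sum(p - 0.5) / dist ** (lambda_ + 1.0) + 0.5)


def choice_prob_pair(preference: float, tau_pair: float) -> float:
    """Logistic choice probability from a pair-level preference.

    The logistic is applied to the preference's deviation from
    indifference, ``(p - 0.5) / tau_pair``, so that p = 0.5 maps to a
    chance-level choice and the arbitration rule's notion of preference
    strength (distance from 0.5) is preserved on the probability scale.
    """
    if tau_pair <= 0:
        raise ValueError("tau_pair must be positive")
    if not 0.0 <= preference <= 1.0:
        raise ValueError("preference must lie in [0, 1]")
    return float(1.0 / (1.0 + math.exp(-(preference - 0.5) / tau_pair)))


def arbitrate(cp_item: float, cp_pair: float) -> tuple:
    """Pick the stronger of the two systems' choice probabilities.

    Returns ``(probability, source)`` with source "item" or "pair".
    Strength is the absolute deviation from 0.5; exact ties go to the
    item-level system (a measure-zero event for continuous parameters).
    """
    for cp in (cp_item, cp_pair):
        if not 0.0 <= cp <= 1.0:
            raise ValueError("choice probabilities must lie in [0, 1]")
    if abs(cp_item - 0.5) >= abs(cp_pair - 0.5):
        return cp_item, "item"
    return cp_pair, "pair"


def resolve_attribution(
    winner: int, loser: int, chosen: int, unchosen: int, mode: str
) -> tuple:
    """Map the two learning rates onto items.

    Returns ``(item_plus, item_minus)``: the items whose updates use
    alpha_plus and alpha_minus respectively. In ``winner_loser`` mode the
    rates follow the feedback outcome; in ``chosen_unchosen`` mode they
    follow the agent's own response, while the update equations (winner
    towards +1-like, loser towards -1-like targets) still follow the
    outcome.
    """
    if {winner, loser} != {chosen, unchosen}:
        raise ValueError("chosen/unchosen must be the same items as winner/loser")
    if mode == "winner_loser":
        return winner, loser
    if mode == "chosen_unchosen":
        return chosen, unchosen
    raise ValueError(f"unknown attribution mode {mode!r}")


# ---------------------------------------------------------------------------
# model space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A named restriction of the most flexible model.

    ``free_params`` are the names exposed to the optimiser, in order; the
    special name ``"alpha"`` ties alpha_plus = alpha_minus (symmetric
    variants). ``fixed_params`` pins the remaining parameters.
    """

    name: str
    free_params: tuple
    fixed_params: dict

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_params)

    @property
    def symmetric(self) -> bool:
        return "alpha" in self.free_params

    @property
    def uses_pair(self) -> bool:
        """Whether the pair-memory system is active (gamma not fixed to 0)."""
        return self.fixed_params.get("gamma", None) != 0.0

    @property
    def uses_item(self) -> bool:
        return not (
            self.fixed_params.get("alpha_plus") == 0.0
            and self.fixed_params.get("alpha_minus") == 0.0
        )

    def bounds(self, negative_rates: bool = False) -> list:
        """Optimisation box, one (lo, hi) per free parameter."""
        out = []
        for name in self.free_params:
            if negative_rates and name in ("alpha", "alpha_plus", "alpha_minus"):
                out.append(NEGATIVE_ALPHA_BOUNDS)
            else:
                out.append(DEFAULT_BOUNDS[name])
        return out

    def make_params(self, values, attribution: str = "winner_loser") -> AgentParams:
        """Build an :class:`AgentParams` from free-parameter values.

        ``values`` is a mapping or a sequence aligned with
        ``free_params``.
        """
        if not isinstance(values, dict):
            values = dict(zip(self.free_params, values, strict=True))
        else:
            unknown = set(values) - set(self.free_params)
            if unknown:
                raise ValueError(f"not free parameters of {self.name}: {sorted(unknown)}")
        full = dict(self.fixed_params)
        for name, v in values.items():
            if name == "alpha":
                full["alpha_plus"] = full["alpha_minus"] = float(v)
            else:
                full[name] = float(v)
        return AgentParams(attribution=attribution, **full)


def _spec(name, free, **fixed) -> ModelSpec:
    defaults = {
        "eta": 0.0,
        "gamma": 0.0,
        "lambda_": LAMBDA_SENTINEL,
        "tau_pair": 0.1,
        "tau_item": 1.0,
    }
    fixed = {**defaults, **fixed}
    resolved = {}
    for key in ("alpha_plus", "alpha_minus", "eta", "tau_item", "gamma", "lambda_", "tau_pair"):
        if key in fixed:
            resolved[key] = fixed[key]
    free = tuple(free)
    tied = {"alpha": ("alpha_plus", "alpha_minus")}
    for f in free:
        for covered in tied.get(f, (f,)):
            resolved.pop(covered, None)
    return ModelSpec(name, free, resolved)


#: Registry of named model variants. Naming: Q = item-level learning,
#: 1/2 = symmetric/asymmetric learning rates, * = difference-weighted
#: updating (eta free), P = pair memory, Pi = pair memory with chained
#: transitive inference (lambda_ free).
MODELS = {
    "Q1": _spec("Q1", ("alpha", "tau_item")),
    "Q2": _spec("Q2", ("alpha_plus", "alpha_minus", "tau_item")),
    "Q1*": _spec("Q1*", ("alpha", "eta", "tau_item")),
    "Q2*": _spec("Q2*", ("alpha_plus", "alpha_minus", "eta", "tau_item")),
    "P": _spec("P", ("gamma", "tau_pair"), alpha_plus=0.0, alpha_minus=0.0),
    "Pi": _spec("Pi", ("gamma", "lambda_", "tau_pair"), alpha_plus=0.0, alpha_minus=0.0),
    "Q1*+P": _spec("Q1*+P", ("alpha", "eta", "tau_item", "gamma", "tau_pair")),
    "Q2*+P": _spec(
        "Q2*+P",
        ("alpha_plus", "alpha_minus", "eta", "tau_item", "gamma", "tau_pair"),
    ),
    "Q1*+Pi": _spec(
        "Q1*+Pi", ("alpha", "eta", "tau_item", "gamma", "lambda_", "tau_pair")
    ),
    "Q2*+Pi": _spec(
        "Q2*+Pi",
        ("alpha_plus", "alpha_minus", "eta", "tau_item", "gamma", "lambda_", "tau_pair"),
    ),
}

#: The eight-model comparison family (item-level models and mixtures).
FAMILY8 = ["Q1", "Q2", "Q1*", "Q2*", "Q1*+P", "Q2*+P", "Q1*+Pi", "Q2*+Pi"]


def get_model(name_or_spec) -> ModelSpec:
    if isinstance(name_or_spec, ModelSpec):
        return name_or_spec
    try:
        return MODELS[name_or_spec]
    except KeyError:
        raise ValueError(
            f"unknown model {name_or_spec!r}; available: {sorted(MODELS)}"
        ) from None
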