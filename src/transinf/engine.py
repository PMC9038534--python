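"""Trial-replay engine (numba-compiled kernels).

The same sequential model dynamics power three front ends: closed-loop
simulation (:mod:`transinf.simulate`), likelihood evaluation
(:mod:`transinf.fitting`) and learning-rate sweeps. The trial loop is
inherently sequential, but everything is computed over a batch axis S:
S can index differential-evolution population members (fitting), grid
cells sharing one trial sequence (sweeps) or independent agents. The
two kernels are compiled with numba (cached across sessions).

Scalar reference implementations of every update live in
:mod:`transinf.models`; the unit tests assert that this engine
reproduces them step for step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .models import AgentParams, ModelSpec

__all__ = ["TrialArrays", "BatchParams", "compile_trials", "replay_nll", "simulate_batch"]

#: Choice probabilities are clipped to this floor before taking logs,
#: guarding the likelihood against underflow at near-zero temperatures.
CP_FLOOR = 1e-9


@dataclass(frozen=True)
class TrialArrays:
    """A trial sequence unpacked into flat numpy arrays (0-based items)."""

    hi: np.ndarray  # higher-ranked item index, 0-based
    lo: np.ndarray
    dist: np.ndarray  # rank distance lo - hi (>= 1)
    feedback: np.ndarray  # bool
    truthful: np.ndarray  # bool, winner == hi (defined where feedback)
    chosen_hi: Optional[np.ndarray]  # bool, observed choice (None if unset)
    n_items: int

    @property
    def n_trials(self) -> int:
        return len(self.hi)


def compile_trials(df, n_items: int, with_choices: bool = False) -> TrialArrays:
    """Convert a trial table (see :mod:`transinf.task_env`) to arrays."""
    hi = df["item_hi"].to_numpy(dtype=np.int64) - 1
    lo = df["item_lo"].to_numpy(dtype=np.int64) - 1
    feedback = df["feedback_scheduled"].to_numpy(dtype=bool)
    truthful = np.zeros(len(df), dtype=np.bool_)
    if feedback.any():
        t = df["truthful"].to_numpy(dtype=object)
        truthful[feedback] = np.array([bool(x) for x in t[feedback]], dtype=bool)
    chosen_hi = None
    if with_choices:
        choice = df["choice"].to_numpy(dtype=np.int64) - 1
        chosen_hi = choice == hi
    return TrialArrays(
        hi=hi,
        lo=lo,
        dist=lo - hi,
        feedback=feedback,
        truthful=truthful,
        chosen_hi=chosen_hi,
        n_items=n_items,
    )


@dataclass
class BatchParams:
    """Parameter arrays broadcast over the batch axis S."""

    alpha_plus: np.ndarray
    alpha_minus: np.ndarray
    eta: np.ndarray
    tau_item: np.ndarray
    gamma: np.ndarray
    lambda_: np.ndarray
    tau_pair: np.ndarray
    chosen_unchosen: bool
    uses_pair: bool
    S: int

    @classmethod
    def from_params(cls, params: AgentParams, S: int = 1, uses_pair=None) -> "BatchParams":
        if uses_pair is None:
            uses_pair = params.gamma != 0.0
        mk = lambda v: np.full(S, float(v))
        return cls(
            alpha_plus=mk(params.alpha_plus),
            alpha_minus=mk(params.alpha_minus),
            eta=mk(params.eta),
            tau_item=mk(params.tau_item),
            gamma=mk(params.gamma),
            lambda_=mk(params.lambda_),
            tau_pair=mk(params.tau_pair),
            chosen_unchosen=params.attribution == "chosen_unchosen",
            uses_pair=uses_pair,
            S=S,
        )

    @classmethod
    def from_population(
        cls,
        spec: ModelSpec,
        population: np.ndarray,
        attribution: str = "winner_loser",
    ) -> "BatchParams":
        """Build batch parameters from a (k, S) optimiser population."""
        population = np.atleast_2d(np.asarray(population, dtype=float))
        if population.shape[0] != spec.k:
            raise ValueError(
                f"population has {population.shape[0]} rows, expected {spec.k}"
            )
        S = population.shape[1]
        vals = {}
        for name, row in zip(spec.free_params, population):
            if name == "alpha":
                vals["alpha_plus"] = row
                vals["alpha_minus"] = row
            else:
                vals[name] = row
        for name, v in spec.fixed_params.items():
            vals[name] = np.full(S, float(v))
        return cls(
            alpha_plus=np.ascontiguousarray(vals["alpha_plus"], dtype=float),
            alpha_minus=np.ascontiguousarray(vals["alpha_minus"], dtype=float),
            eta=np.ascontiguousarray(vals["eta"], dtype=float),
            tau_item=np.ascontiguousarray(vals["tau_item"], dtype=float),
            gamma=np.ascontiguousarray(vals["gamma"], dtype=float),
            lambda_=np.ascontiguousarray(vals["lambda_"], dtype=float),
            tau_pair=np.ascontiguousarray(vals["tau_pair"], dtype=float),
            chosen_unchosen=attribution == "chosen_unchosen",
            uses_pair=spec.uses_pair,
            S=S,
        )


@njit(cache=True, fastmath=False)
def _sigmoid(x):
    if x > 60.0:
        x = 60.0
    elif x < -60.0:
        x = -60.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=False)
def _cp_hi(Q, U, L, s, h, l, d, tau_i, tau_p, lam, uses_pair):
    """Arbitrated probability of choosing the truly higher item."""
    cpi = _sigmoid((Q[s, h] - Q[s, l]) / tau_i)
    if not uses_pair:
        return cpi
    pref = 0.0
    for n in range(h, l):
        pref += U[s, n] / (U[s, n] + L[s, n]) - 0.5
    if d > 1:
        pref /= d ** (lam + 1.0)
    cpp = _sigmoid(pref / tau_p)
    # ties go to the item-level system
    if abs(cpp - 0.5) > abs(cpi - 0.5):
        return cpp
    return cpi


@njit(cache=True, fastmath=False)
def _update(Q, U, L, s, h, l, d, truthful, chose_hi, ap, am, eta, gamma,
            uses_pair, chosen_unchosen):
    """In-place state change after one feedback event."""
    if truthful:
        w, lo_ = h, l
    else:
        w, lo_ = l, h
    a_w, a_l = ap, am
    if chosen_unchosen:
        chose_winner = chose_hi == (w == h)
        if not chose_winner:
            a_w, a_l = am, ap
    qw = Q[s, w]
    ql = Q[s, lo_]
    dd = eta * (qw - ql)
    Q[s, w] = qw + a_w * (1.0 - dd - qw)
    Q[s, lo_] = ql + a_l * (-1.0 + dd - ql)
    if uses_pair and d == 1:
        if truthful:
            U[s, h] += gamma
        else:
            L[s, h] += gamma


@njit(cache=True, fastmath=False)
def _nll_kernel(hi, lo, dist, fb, truthful, chosen, n_items,
                ap, am, eta, ti, gamma, lam, tp, uses_pair, chosen_unchosen):
    S = ap.shape[0]
    T = hi.shape[0]
    Q = np.zeros((S, n_items))
    U = np.ones((S, n_items - 1))
    L = np.ones((S, n_items - 1))
    nll = np.zeros(S)
    for t in range(T):
        h, l, d = hi[t], lo[t], dist[t]
        for s in range(S):
            cp = _cp_hi(Q, U, L, s, h, l, d, ti[s], tp[s], lam[s], uses_pair)
            p = cp if chosen[t] else 1.0 - cp
            if p < CP_FLOOR:
                p = CP_FLOOR
            elif p > 1.0 - CP_FLOOR:
                p = 1.0 - CP_FLOOR
            nll[s] -= np.log(p)
            if fb[t]:
                _update(Q, U, L, s, h, l, d, truthful[t], chosen[t],
                        ap[s], am[s], eta[s], gamma[s], uses_pair,
                        chosen_unchosen)
    return nll


@njit(cache=True, fastmath=False)
def _sim_kernel(hi, lo, dist, fb, truthful, n_items, u_rand,
                ap, am, eta, ti, gamma, lam, tp, uses_pair, chosen_unchosen,
                record_cp, record_q):
    S = ap.shape[0]
    T = hi.shape[0]
    Q = np.zeros((S, n_items))
    U = np.ones((S, n_items - 1))
    L = np.ones((S, n_items - 1))
    chosen_hi = np.zeros((T, S), dtype=np.bool_)
    cp_rec = np.zeros((T, S)) if record_cp else np.zeros((1, 1))
    q_rec = np.zeros((T, S, n_items)) if record_q else np.zeros((1, 1, 1))
    for t in range(T):
        h, l, d = hi[t], lo[t], dist[t]
        for s in range(S):
            cp = _cp_hi(Q, U, L, s, h, l, d, ti[s], tp[s], lam[s], uses_pair)
            choice = u_rand[t, s] < cp
            chosen_hi[t, s] = choice
            if record_cp:
                cp_rec[t, s] = cp
            if fb[t]:
                _update(Q, U, L, s, h, l, d, truthful[t], choice,
                        ap[s], am[s], eta[s], gamma[s], uses_pair,
                        chosen_unchosen)
        if record_q:
            q_rec[t] = Q
    return chosen_hi, Q, U, L, cp_rec, q_rec


def replay_nll(trials: TrialArrays, bp: BatchParams) -> np.ndarray:
    """Negative log-likelihood of the recorded choices, shape (S,).

    Replays the session: each trial's choice probability is computed from
    the state *before* that trial's update, and feedback is applied
    exactly as recorded. All trials contribute to the likelihood;
    no-feedback trials trigger no state change.
    """
    if trials.chosen_hi is None:
        raise ValueError("trial arrays carry no recorded choices")
    return _nll_kernel(
        trials.hi, trials.lo, trials.dist, trials.feedback, trials.truthful,
        trials.chosen_hi, trials.n_items,
        bp.alpha_plus, bp.alpha_minus, bp.eta, bp.tau_item, bp.gamma,
        bp.lambda_, bp.tau_pair, bp.uses_pair, bp.chosen_unchosen,
    )


def simulate_batch(
    trials: TrialArrays,
    bp: BatchParams,
    rng: np.random.Generator,
    record_cp: bool = False,
    record_q: bool = False,
):
    """Closed-loop simulation of S agents/cells on one trial sequence.

    Choices are sampled from each batch member's own arbitration
    probability; feedback outcomes come from the pre-sampled sequence
    (they do not depend on the choice). Returns a dict with boolean
    arrays ``chosen_hi`` and ``correct`` of shape (T, S), the final
    ``q_values`` (S, n_items) and pair counts, plus optional per-trial
    choice probabilities ``cp_hi`` and Q trajectories.
    """
    u_rand = rng.random((trials.n_trials, bp.S))
    chosen_hi, Q, U, L, cp_rec, q_rec = _sim_kernel(
        trials.hi, trials.lo, trials.dist, trials.feedback, trials.truthful,
        trials.n_items, u_rand,
        bp.alpha_plus, bp.alpha_minus, bp.eta, bp.tau_item, bp.gamma,
        bp.lambda_, bp.tau_pair, bp.uses_pair, bp.chosen_unchosen,
        record_cp, record_q,
    )
    out = {
        "chosen_hi": chosen_hi,
        "correct": chosen_hi,  # choosing the truly higher item is correct
        "q_values": Q,
        "pair_u": U,
        "pair_l": L,
    }
    if record_cp:
        out["cp_hi"] = cp_rec
    if record_q:
        out["q_traj"] = q_rec
    return out
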