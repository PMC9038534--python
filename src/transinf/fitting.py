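"""Maximum-likelihood model fitting and per-participant fit statistics.

Parameters are estimated by minimising the negative log-likelihood of a
participant's single-trial responses over the model's free-parameter box
with differential evolution (a global, derivative-free optimiser; the
likelihood surface of these sequential learners is multimodal). The
likelihood replays the session: each trial's choice probability is
computed from the learner state *before* that trial, and feedback enters
the state exactly as recorded in the dataset. All trials contribute to
the likelihood; trials without feedback trigger no state update.

Fit quality is summarised by BIC = k ln N + 2 NLL, by a chance-anchored
pseudo-R^2 = 1 - BIC_model / BIC_null (null: always-guessing model with
zero free parameters), and by the learning-rate asymmetry index
A = (alpha_plus - alpha_minus) / |alpha_plus + alpha_minus|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import differential_evolution, minimize

from . import engine
from .models import AgentParams, get_model

__all__ = [
    "FitResult",
    "negative_log_likelihood",
    "null_bic",
    "pseudo_r2",
    "asymmetry_index",
    "fit_model",
]


@dataclass
class FitResult:
    participant: str
    model_name: str
    params: dict  # free-parameter estimates, by name
    nll: float
    bic: float
    pseudo_r2: float
    asymmetry_index: float  # NaN when undefined
    n_trials: int
    k: int
    n_iterations: int
    converged: bool
    seed: Optional[int] = None

    def as_row(self) -> dict:
        row = {
            "participant": self.participant,
            "model": self.model_name,
            "nll": self.nll,
            "bic": self.bic,
            "pseudo_r2": self.pseudo_r2,
            "asymmetry_index": self.asymmetry_index,
            "n_trials": self.n_trials,
            "k": self.k,
            "converged": self.converged,
        }
        row.update(self.params)
        return row


def _trial_arrays(dataset) -> engine.TrialArrays:
    df = dataset.trials if hasattr(dataset, "trials") else dataset
    n_items = int(max(df["item_hi"].max(), df["item_lo"].max()))
    return engine.compile_trials(df, n_items, with_choices=True)


def negative_log_likelihood(
    dataset, model, params, attribution: str = "winner_loser"
) -> float:
    """NLL (nats) of one dataset under one parameterisation.

    ``params`` may be an :class:`AgentParams`, a mapping of free
    parameters, or a sequence aligned with the model's free parameters.
    """
    spec = get_model(model)
    if isinstance(params, AgentParams):
        bp = engine.BatchParams.from_params(params, S=1, uses_pair=spec.uses_pair)
        bp.chosen_unchosen = params.attribution == "chosen_unchosen"
    else:
        if isinstance(params, dict):
            params = [params[name] for name in spec.free_params]
        pop = np.asarray(params, dtype=float).reshape(spec.k, 1)
        bp = engine.BatchParams.from_population(spec, pop, attribution)
    ta = _trial_arrays(dataset)
    return float(engine.replay_nll(ta, bp)[0])


def null_bic(n_trials: int) -> float:
    """BIC of the zero-parameter chance model (CP = 0.5 on every trial)."""
    return 2.0 * n_trials * math.log(2.0)


def pseudo_r2(bic_model: float, bic_null: float) -> float:
    """Chance-anchored goodness of fit: 1 - BIC_model / BIC_null.

    0 for a model no better than guessing, 1 for a theoretically perfect
    model (NLL -> 0 with no free parameters), negative when the model
    underperforms chance after complexity penalisation.
    """
    if bic_null <= 0:
        raise ValueError("bic_null must be positive")
    return 1.0 - bic_model / bic_null


def asymmetry_index(alpha_plus: float, alpha_minus: float) -> float:
    """Normalised learning-rate asymmetry (alpha+ - alpha-)/|alpha+ + alpha-|.

    +1 means pure winner updating, -1 pure loser updating, 0 symmetric.
    The +/-1 range holds for non-negative rates; with negative rates the
    index can exceed it. Undefined (NaN) when the rates cancel exactly.
    """
    denom = abs(alpha_plus + alpha_minus)
    if denom == 0.0:
        return float("nan")
    return (alpha_plus - alpha_minus) / denom


def fit_model(
    dataset,
    model,
    seed: int = 0,
    bounds: Optional[list] = None,
    negative_rates: bool = False,
    attribution: str = "winner_loser",
    maxiter: int = 200,
    popsize: int = 15,
    tol: float = 0.01,
    init: str = "latinhypercube",
    polish: bool = True,
) -> FitResult:
    """Fit one model to one participant's dataset.

    Differential evolution is run over the model's free-parameter box
    (uniform initialisation, seeded, best/1/bin strategy) with the whole
    population evaluated in one vectorised likelihood call per
    generation, followed by a deterministic local polish (L-BFGS-B) of
    the best member. ``negative_rates`` widens the learning-rate box to
    [-0.2, 0.2]. Non-convergence within ``maxiter`` generations is
    flagged on the result, never silently dropped.
    """
    spec = get_model(model)
    ta = _trial_arrays(dataset)
    if bounds is None:
        bounds = spec.bounds(negative_rates=negative_rates)
    if len(bounds) != spec.k:
        raise ValueError(f"expected {spec.k} bounds for {spec.name}")

    def objective(x):
        pop = x if x.ndim == 2 else x.reshape(-1, 1)
        bp = engine.BatchParams.from_population(spec, pop, attribution)
        out = engine.replay_nll(ta, bp)
        return out if x.ndim == 2 else out[0]

    res = differential_evolution(
        objective,
        bounds=bounds,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=tol,
        init=init,
        updating="deferred",
        vectorized=True,
        polish=False,
    )
    x_best, f_best = np.asarray(res.x, dtype=float), float(res.fun)
    if polish:
        # local refinement; the forward-difference gradient is obtained
        # from a single vectorised likelihood call per L-BFGS-B step
        h = 1e-7
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        steps = h * np.maximum(1.0, np.abs(hi - lo))

        def fun_and_grad(x):
            pts = np.tile(x[:, None], (1, spec.k + 1))
            signed = np.empty(spec.k)
            for i in range(spec.k):
                # step inward at the upper bound
                signed[i] = steps[i] if x[i] + steps[i] <= hi[i] else -steps[i]
                pts[i, i + 1] += signed[i]
            vals = objective(pts)
            return vals[0], (vals[1:] - vals[0]) / signed

        loc = minimize(
            fun_and_grad,
            x_best,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 100},
        )
        if np.isfinite(loc.fun) and loc.fun < f_best:
            x_best, f_best = np.clip(loc.x, lo, hi), float(loc.fun)
    est = dict(zip(spec.free_params, (float(v) for v in x_best)))
    nll = f_best
    n = ta.n_trials
    bic = spec.k * math.log(n) + 2.0 * nll
    if "alpha" in est:
        asym = 0.0 if est["alpha"] != 0 else float("nan")
    elif "alpha_plus" in est:
        asym = asymmetry_index(est["alpha_plus"], est["alpha_minus"])
    else:
        asym = float("nan")
    participant = getattr(dataset, "participant", "unknown")
    return FitResult(
        participant=participant,
        model_name=spec.name,
        params=est,
        nll=nll,
        bic=bic,
        pseudo_r2=pseudo_r2(bic, null_bic(n)),
        asymmetry_index=asym,
        n_trials=n,
        k=spec.k,
        n_iterations=int(res.nit),
        converged=bool(res.success),
        seed=seed,
    )
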