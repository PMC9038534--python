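"""Group-level model comparison and recovery harnesses.

Model comparison follows random-effects Bayesian model selection:
per-participant model evidences (approximated as -BIC/2) feed a
variational estimate of the population frequencies of the candidate
models (Dirichlet posterior), from which exceedance probabilities are
obtained by Monte-Carlo sampling and protected against the null
hypothesis of indistinguishable models via the Bayesian omnibus risk:

    pxp_k = (1 - BOR) * xp_k + BOR / K.

Recovery harnesses quantify identifiability: *model recovery* simulates
datasets from each model, refits the whole family and tabulates the
confusion matrix p(fit|gen), inverted by Bayes's rule under a uniform
prior over generating models into p(gen|fit); *parameter recovery*
varies each generative parameter over a grid, refits, and correlates
generative with recovered values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from . import cohort as cohort_mod
from . import task_env
from .fitting import fit_model
from .models import FAMILY8, get_model
from .simulate import simulate_agent

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "protected_exceedance",
    "compare_models",
    "RecoveryReport",
    "model_recovery",
    "parameter_recovery",
]


@dataclass
class ComparisonResult:
    models: list
    pxp: np.ndarray
    xp: np.ndarray
    bor: float
    expected_freq: np.ndarray
    alpha: np.ndarray
    mean_bic: np.ndarray
    sem_bic: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "pxp": self.pxp,
                "xp": self.xp,
                "expected_freq": self.expected_freq,
                "mean_bic": self.mean_bic,
                "sem_bic": self.sem_bic,
            }
        )


def _dirichlet_entropy(alpha: np.ndarray) -> float:
    a0 = alpha.sum()
    K = len(alpha)
    ln_b = gammaln(alpha).sum() - gammaln(a0)
    return float(
        ln_b + (a0 - K) * digamma(a0) - np.sum((alpha - 1.0) * digamma(alpha))
    )


def protected_exceedance(
    bic: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
    alpha0: float = 1.0,
    max_iter: int = 10_000,
    tol: float = 1e-10,
) -> ComparisonResult:
    """Random-effects model selection from a participants x models BIC matrix.

    Log-evidences are approximated as -BIC/2. A variational Dirichlet
    posterior over population model frequencies is estimated, exceedance
    probabilities are computed by Dirichlet sampling, and protection
    applies the Bayesian-omnibus-risk mixture with the chance level 1/K.
    Degenerate input (identical evidences everywhere) yields the uniform
    answer rather than an error.
    """
    bic = np.asarray(bic, dtype=float)
    if bic.ndim != 2 or bic.shape[1] < 2 or bic.shape[0] < 1:
        raise ValueError("need a (participants, >=2 models) BIC matrix")
    N, K = bic.shape
    L = -bic / 2.0

    alpha = np.full(K, alpha0)
    for _ in range(max_iter):
        w = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha

    # exceedance probabilities by sampling the Dirichlet posterior
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    xp = np.bincount(winners, minlength=K) / n_samples

    # Bayesian omnibus risk: P(H0: frequencies are uniform | data)
    # F1: variational free energy of the random-effects model
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        g_ln_g = np.where(g > 0, g * np.log(g), 0.0)
    f1 = (
        float(np.sum(g * L))
        + float(np.sum(g * elog_r))
        - float(np.sum(g_ln_g))
        + float(gammaln(K * alpha0) - K * gammaln(alpha0))
        + _dirichlet_entropy(alpha)
    )
    # F0: evidence under the null (every participant, uniform model prob.)
    f0 = float(np.sum(logsumexp(L - np.log(K), axis=1)))
    bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    pxp = (1.0 - bor) * xp + bor / K

    return ComparisonResult(
        models=list(range(K)),
        pxp=pxp,
        xp=xp,
        bor=bor,
        expected_freq=alpha / alpha.sum(),
        alpha=alpha,
        mean_bic=bic.mean(axis=0),
        sem_bic=bic.std(axis=0, ddof=1) / np.sqrt(N) if N > 1 else np.full(K, np.nan),
    )


def compare_models(fit_table: pd.DataFrame, seed: int = 0) -> ComparisonResult:
    """Comparison from a long fit table with participant/model/bic columns."""
    wide = fit_table.pivot(index="participant", columns="model", values="bic")
    if wide.isna().any().any():
        missing = wide.isna().sum().to_dict()
        raise ValueError(f"missing fits per model: {missing}")
    res = protected_exceedance(wide.to_numpy(), seed=seed)
    res.models = list(wide.columns)
    return res


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    models: list
    counts: np.ndarray  # gen x fit best-fit counts
    p_fit_given_gen: pd.DataFrame  # rows sum to 1
    p_gen_given_fit: pd.DataFrame  # columns sum to 1
    n_failed: int = 0

    @staticmethod
    def from_counts(models: Sequence[str], counts: np.ndarray, n_failed=0):
        counts = np.asarray(counts, dtype=float)
        row_tot = counts.sum(axis=1, keepdims=True)
        p_fg = np.divide(counts, row_tot, out=np.zeros_like(counts), where=row_tot > 0)
        # Bayes inversion with a uniform prior over generating models
        col_tot = p_fg.sum(axis=0, keepdims=True)
        p_gf = np.divide(p_fg, col_tot, out=np.zeros_like(p_fg), where=col_tot > 0)
        models = list(models)
        return RecoveryReport(
            models=models,
            counts=counts.astype(int),
            p_fit_given_gen=pd.DataFrame(p_fg, index=models, columns=models),
            p_gen_given_fit=pd.DataFrame(p_gf, index=models, columns=models),
            n_failed=n_failed,
        )


def default_generating_dists(model_name: str) -> dict:
    """Generating parameter distributions per model for recovery runs.

    Asymmetric models generate winner-biased learners, the configuration
    under which the model family is maximally distinguishable under
    partial feedback; symmetric models use a matched single rate.
    Distributions follow the cohort profiles (see
    :data:`transinf.cohort.PROFILES`), with mild jitter so repeated runs
    are not degenerate.
    """
    g = cohort_mod.gaussian
    dists = {
        "alpha": g(0.05, 0.015, lo=0.01, hi=0.2),
        "alpha_plus": g(0.063, 0.015, lo=0.02, hi=0.2),
        "alpha_minus": g(0.01, 0.005, lo=0.0, hi=0.2),
        "eta": g(3.0, 0.5, lo=0.5),
        "tau_item": g(0.04, 0.01, lo=0.02, hi=0.2),
        "gamma": g(0.5, 0.1, lo=0.1, hi=1.0),
        "tau_pair": g(0.1, 0.02, lo=0.05, hi=0.3),
        "lambda_": g(1.0, 0.3, lo=0.0, hi=3.0),
    }
    spec = get_model(model_name)
    return {name: dists[name] for name in spec.free_params}


def model_recovery(
    design="exp2",
    models: Sequence[str] = tuple(FAMILY8),
    runs_per_model: int = 10,
    seed: int = 0,
    fit_kwargs: Optional[dict] = None,
    generating_dists: Optional[dict] = None,
) -> RecoveryReport:
    """Simulate-and-refit confusion analysis over a model family.

    For every model, ``runs_per_model`` datasets are simulated from
    parameters drawn via :func:`default_generating_dists`; each dataset
    is fitted by every model in the family and the best BIC wins. Fit
    failures (non-finite likelihoods) are excluded with a logged count.
    """
    design = task_env.get_design(design)
    models = list(models)
    fit_kwargs = {**RECOVERY_FIT_SETTINGS, **(fit_kwargs or {})}
    counts = np.zeros((len(models), len(models)))
    n_failed = 0
    ss = task_env._as_seedseq(seed)
    for gi, gen_name in enumerate(models):
        spec = get_model(gen_name)
        dists = (
            generating_dists[gen_name]
            if generating_dists is not None
            else default_generating_dists(gen_name)
        )
        for run_ss in ss.spawn(runs_per_model):
            draw_ss, sim_ss, fit_ss = run_ss.spawn(3)
            values = cohort_mod.draw_params(spec, dists, np.random.default_rng(draw_ss))
            sim = simulate_agent(design, spec, values, sim_ss)
            ds = sim.trials
            fit_seed = int(fit_ss.generate_state(1)[0] % (2**31))
            bics = []
            for fit_name in models:
                fr = fit_model(ds, fit_name, seed=fit_seed, **fit_kwargs)
                bics.append(fr.bic if np.isfinite(fr.bic) else np.inf)
            if not np.any(np.isfinite(bics)):
                n_failed += 1
                logger.warning("all fits failed for a %s dataset", gen_name)
                continue
            counts[gi, int(np.argmin(bics))] += 1
    return RecoveryReport.from_counts(models, counts, n_failed=n_failed)


@dataclass
class ParameterRecoveryResult:
    model_name: str
    records: pd.DataFrame  # one row per dataset: gen_*/rec_* columns
    correlations: pd.DataFrame  # generative (rows) x recovered (cols)

    def self_correlations(self) -> pd.Series:
        return pd.Series(np.diag(self.correlations), index=self.correlations.index)


#: Optimiser settings for the recovery harnesses: enough generations at
#: a tight tolerance that repeated fits of the same dataset agree to
#: ~1e-3 nats (fit noise well below the sampling noise of the study).
RECOVERY_FIT_SETTINGS = {"maxiter": 300, "popsize": 25, "tol": 1e-4}


def parameter_recovery(
    design="exp2",
    model="Q2*+P",
    base_params: Optional[dict] = None,
    n_values: int = 20,
    datasets_per_value: int = 3,
    seed: int = 0,
    fit_kwargs: Optional[dict] = None,
) -> ParameterRecoveryResult:
    """Grid-based parameter identifiability analysis.

    Each free parameter in turn is varied over ``n_values`` evenly
    spaced values within its fitting bounds while the others stay at
    ``base_params`` (default: an empirically plausible winner-updating
    configuration); ``datasets_per_value`` sessions are simulated per
    grid point and refitted. The grid uses bin midpoints of the bounded
    interval (strictly interior): at a boundary such as gamma = 0 the
    varied parameter would drop out of the generative model entirely,
    making its recovered value arbitrary rather than informative. The
    correlation matrix row for parameter p correlates p's generative
    grid against every recovered parameter over p's datasets; undefined
    correlations (zero variance) are NaN.
    """
    design = task_env.get_design(design)
    spec = get_model(model)
    fit_kwargs = {**RECOVERY_FIT_SETTINGS, **(fit_kwargs or {})}
    if base_params is None:
        base_params = {
            "alpha_plus": 0.063,
            "alpha_minus": 0.01,
            "alpha": 0.04,
            "eta": 3.0,
            "tau_item": 0.04,
            "gamma": 0.5,
            "lambda_": 1.0,
            "tau_pair": 0.1,
        }
    base = {
        name: base_params[name] for name in spec.free_params
    }

    bounds = dict(zip(spec.free_params, spec.bounds()))
    rows = []
    ss = task_env._as_seedseq(seed)
    for name in spec.free_params:
        lo, hi = bounds[name]
        edges = np.linspace(lo, hi, n_values + 1)
        grid = (edges[:-1] + edges[1:]) / 2.0
        for v in grid:
            gen = dict(base)
            gen[name] = float(v)
            for ds_ss in ss.spawn(datasets_per_value):
                sim_ss, fit_ss = ds_ss.spawn(2)
                sim = simulate_agent(design, spec, gen, sim_ss)
                fit_seed = int(fit_ss.generate_state(1)[0] % (2**31))
                fr = fit_model(sim.trials, spec, seed=fit_seed, **fit_kwargs)
                row = {"varied": name}
                row.update({f"gen_{k}": gen[k] for k in spec.free_params})
                row.update({f"rec_{k}": fr.params[k] for k in spec.free_params})
                rows.append(row)
    records = pd.DataFrame(rows)

    corr = pd.DataFrame(
        np.nan, index=list(spec.free_params), columns=list(spec.free_params)
    )
    for gen_name in spec.free_params:
        sub = records[records["varied"] == gen_name]
        x = sub[f"gen_{gen_name}"].to_numpy()
        if np.std(x) == 0:
            continue
        for rec_name in spec.free_params:
            y = sub[f"rec_{rec_name}"].to_numpy()
            if np.std(y) == 0:
                continue
            corr.loc[gen_name, rec_name] = float(np.corrcoef(x, y)[0, 1])
    return ParameterRecoveryResult(spec.name, records, corr)
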