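"""Closed-loop agent simulation, learning-rate sweeps and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import engine, task_env
from .models import AgentParams, get_model

__all__ = [
    "SimulationResult",
    "GridSweepResult",
    "simulate_agent",
    "sweep_learning_rates",
    "pair_category",
    "pair_categories",
    "learning_curves",
    "value_compression_index",
]


@dataclass
class SimulationResult:
    """One agent's simulated session.

    ``trials`` is the environment's trial table augmented with the
    agent's ``choice`` (item id), ``correct`` flag (choice equals the
    truly higher item) and model choice probability ``cp_hi`` for the
    higher item. ``q_final`` holds the end-of-session item values;
    ``q_traj`` (T, n_items) is recorded on request.
    """

    design_name: str
    model_name: str
    params: AgentParams
    trials: pd.DataFrame
    q_final: np.ndarray
    pair_u: np.ndarray
    pair_l: np.ndarray
    q_traj: Optional[np.ndarray] = None

    @property
    def accuracy(self) -> float:
        return float(self.trials["correct"].mean())

    def accuracy_where(self, mask) -> float:
        return float(self.trials.loc[mask, "correct"].mean())

    def choice_matrix(self) -> np.ndarray:
        """Mean probability of choosing row item over column item.

        Averaged over the trials on which each unordered pair was shown;
        antisymmetric about 0.5 (M[i,j] + M[j,i] = 1), NaN on the
        diagonal and for pairs never presented.
        """
        n = len(self.q_final)
        M = np.full((n, n), np.nan)
        g = self.trials.groupby(["item_hi", "item_lo"])["cp_hi"].mean()
        for (hi, lo), cp in g.items():
            M[hi - 1, lo - 1] = cp
            M[lo - 1, hi - 1] = 1.0 - cp
        return M


def simulate_agent(
    design,
    model,
    params,
    seed,
    record_q: bool = False,
) -> SimulationResult:
    """Simulate one agent of ``model`` on a fresh session of ``design``.

    ``params`` may be an :class:`AgentParams` or a mapping of the model's
    free parameters. The seed is split into independent streams for the
    trial sequence (order + feedback) and the agent's choice sampling.
    Agents start from flat priors, so the first choice is a coin flip.
    """
    design = task_env.get_design(design)
    spec = get_model(model)
    if not isinstance(params, AgentParams):
        params = spec.make_params(params)
    ss = task_env._as_seedseq(seed)
    seq_ss, choice_ss = ss.spawn(2)
    trials = task_env.build_trial_sequence(design, seq_ss)
    ta = engine.compile_trials(trials, design.n_items)
    bp = engine.BatchParams.from_params(params, S=1, uses_pair=spec.uses_pair)
    rng = np.random.default_rng(choice_ss)
    out = engine.simulate_batch(ta, bp, rng, record_cp=True, record_q=record_q)

    trials = trials.copy()
    chose_hi = out["chosen_hi"][:, 0]
    trials["choice"] = np.where(chose_hi, trials["item_hi"], trials["item_lo"])
    trials["correct"] = chose_hi
    trials["cp_hi"] = out["cp_hi"][:, 0]
    return SimulationResult(
        design_name=design.name,
        model_name=spec.name,
        params=params,
        trials=trials,
        q_final=out["q_values"][0],
        pair_u=out["pair_u"][0],
        pair_l=out["pair_l"][0],
        q_traj=out["q_traj"][:, 0, :] if record_q else None,
    )


@dataclass
class GridSweepResult:
    """Mean second-half accuracy over a learning-rate grid."""

    alpha_plus: np.ndarray  # grid values, axis 0 of performance
    alpha_minus: np.ndarray  # axis 1
    performance: np.ndarray  # (len(alpha_plus), len(alpha_minus))
    design_name: str
    model_name: str
    n_replications: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format, one row per grid cell."""
        ap, am = np.meshgrid(self.alpha_plus, self.alpha_minus, indexing="ij")
        return pd.DataFrame(
            {
                "alpha_plus": ap.ravel(),
                "alpha_minus": am.ravel(),
                "performance": self.performance.ravel(),
            }
        )

    def best_cell(self) -> tuple:
        i, j = np.unravel_index(np.argmax(self.performance), self.performance.shape)
        return float(self.alpha_plus[i]), float(self.alpha_minus[j])

    def plot(self, ax=None):
        """Render the performance surface as a heatmap (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            self.performance,
            origin="lower",
            extent=(
                self.alpha_minus[0], self.alpha_minus[-1],
                self.alpha_plus[0], self.alpha_plus[-1],
            ),
            aspect="auto",
            cmap="viridis",
        )
        ax.set_xlabel(r"$\alpha^-$ (loser)")
        ax.set_ylabel(r"$\alpha^+$ (winner)")
        ax.set_title(f"{self.model_name} on {self.design_name}")
        ax.figure.colorbar(im, ax=ax, label="proportion correct (2nd half)")
        return ax


def default_sweep_grid(step: float = 0.001, upper: float = 0.1) -> np.ndarray:
    """The reference learning-rate grid: 0 to ``upper`` in ``step`` increments."""
    n = int(round(upper / step)) + 1
    return np.linspace(0.0, upper, n)


def sweep_learning_rates(
    design,
    model,
    fixed_params: dict,
    grid: Optional[np.ndarray] = None,
    n_replications: int = 100,
    seed: int = 0,
) -> GridSweepResult:
    """Simulate performance across an (alpha_plus, alpha_minus) grid.

    All grid cells are run in lockstep on the same trial sequence within
    a replication (common random numbers for the environment; each cell
    samples its own choices), and each replication uses a fresh
    sequence. Performance is the mean proportion of correct choices on
    the second half of the trials, averaged over replications. For
    symmetric models the grid is traversed on its diagonal only and the
    result is broadcast, since off-diagonal cells are undefined.
    """
    design = task_env.get_design(design)
    spec = get_model(model)
    if grid is None:
        grid = default_sweep_grid()
    grid = np.asarray(grid, dtype=float)
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")

    if spec.symmetric:
        cells = [(a, a) for a in grid]
    else:
        cells = [(a, b) for a in grid for b in grid]
    S = len(cells)
    pop = {name: np.empty(S) for name in ("alpha_plus", "alpha_minus")}
    pop["alpha_plus"][:] = [c[0] for c in cells]
    pop["alpha_minus"][:] = [c[1] for c in cells]

    # template params; learning rates are overwritten per cell
    base = dict(fixed_params)
    base.setdefault("alpha_plus", 0.0)
    base.setdefault("alpha_minus", 0.0)
    template = AgentParams(**base)

    half = design.n_trials // 2
    acc = np.zeros(S)
    ss = task_env._as_seedseq(seed)
    for rep_ss in ss.spawn(n_replications):
        seq_ss, choice_ss = rep_ss.spawn(2)
        trials = task_env.build_trial_sequence(design, seq_ss)
        ta = engine.compile_trials(trials, design.n_items)
        bp = engine.BatchParams.from_params(template, S=S, uses_pair=spec.uses_pair)
        bp.alpha_plus = pop["alpha_plus"]
        bp.alpha_minus = pop["alpha_minus"]
        rng = np.random.default_rng(choice_ss)
        out = engine.simulate_batch(ta, bp, rng)
        acc += out["correct"][half:].mean(axis=0)
    acc /= n_replications

    if spec.symmetric:
        perf = np.full((len(grid), len(grid)), np.nan)
        np.fill_diagonal(perf, acc)
    else:
        perf = acc.reshape(len(grid), len(grid))
    return GridSweepResult(
        alpha_plus=grid.copy(),
        alpha_minus=grid.copy(),
        performance=perf,
        design_name=design.name,
        model_name=spec.name,
        n_replications=n_replications,
    )


def pair_categories(n_items: int) -> dict:
    """Category of every unordered pair: 'neighbour' or value tercile.

    Non-neighbour pairs are split into three equal-count bins ("high",
    "medium", "low" value) by the mean rank of the two items (small mean
    rank = high value). The high bin is filled from the high-value end
    and the low bin from the low-value end, with mirrored deterministic
    tie-breaking (larger rank distance first), so the partition is
    equivariant under the value-mirror symmetry i -> n+1-i: the low and
    high categories are exact mirror images. A symmetric learner
    therefore shows no low/high performance difference by construction.
    """
    cats = {}
    nn = task_env.nonneighbour_pairs(n_items)
    k = len(nn) // 3
    mean = lambda p: (p[0] + p[1]) / 2.0
    dist = lambda p: p[1] - p[0]
    high = sorted(nn, key=lambda p: (mean(p), -dist(p), p[0]))[:k]
    rest = [p for p in nn if p not in high]
    low = sorted(rest, key=lambda p: (-mean(p), -dist(p), -p[1]))[:k]
    for pair in nn:
        if pair in high:
            cats[pair] = "high"
        elif pair in low:
            cats[pair] = "low"
        else:
            cats[pair] = "medium"
    for pair in task_env.neighbour_pairs(n_items):
        cats[pair] = "neighbour"
    return cats


def pair_category(item_hi: int, item_lo: int, n_items: int) -> str:
    return pair_categories(n_items)[(min(item_hi, item_lo), max(item_hi, item_lo))]


def learning_curves(
    results: Sequence,
    window: int = 150,
    categories: Sequence[str] = ("low", "medium", "high"),
    n_items: int = 8,
) -> pd.DataFrame:
    """Sliding-window accuracy per pair category, averaged over agents.

    ``results`` is a sequence of :class:`SimulationResult` or of trial
    DataFrames carrying ``item_hi, item_lo, correct``. For each window
    end t (from ``window`` to T), accuracy is the mean of ``correct``
    over category trials with index in (t - window, t], pooled across
    agents. Windows in which a category never occurs yield NaN and a
    warning (never a silent drop).

    Returns a tidy frame with columns ``trial, category, accuracy, n``.
    """
    import warnings

    frames = [r.trials if hasattr(r, "trials") else r for r in results]
    T = len(frames[0])
    if window > T or window < 1:
        raise ValueError(f"window must lie in [1, {T}]")
    cats = pair_categories(n_items)
    rows = []
    for cat in categories:
        # stack per-agent indicator series on the common trial grid
        hit = np.zeros(T)
        cnt = np.zeros(T)
        for df in frames:
            pairs = list(zip(df["item_hi"], df["item_lo"]))
            in_cat = np.array([cats[(min(p), max(p))] == cat for p in pairs])
            hit += np.where(in_cat, df["correct"].to_numpy(dtype=float), 0.0)
            cnt += in_cat
        ch = np.concatenate([[0.0], np.cumsum(hit)])
        cc = np.concatenate([[0.0], np.cumsum(cnt)])
        n_win = cc[window:] - cc[:-window]
        acc = np.divide(
            ch[window:] - ch[:-window],
            n_win,
            out=np.full(T - window + 1, np.nan),
            where=n_win > 0,
        )
        if np.any(n_win == 0):
            warnings.warn(
                f"category {cat!r} absent from {int((n_win == 0).sum())} windows",
                stacklevel=2,
            )
        for i, t in enumerate(range(window, T + 1)):
            rows.append((t, cat, acc[i], int(n_win[i])))
    return pd.DataFrame(rows, columns=["trial", "category", "accuracy", "n"])


def value_compression_index(q_values) -> float:
    """Top-half minus bottom-half mean adjacent value gap.

    ``q_values`` are ordered by true rank (highest-valued item first).
    The index contrasts the mean gap between adjacent items within the
    top half against the bottom half; negative values indicate value
    compression at the top of the scale, zero an equally spaced (linear)
    value profile.
    """
    q = np.asarray(q_values, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q_values must be finite")
    n = len(q)
    if n < 4:
        raise ValueError("need at least 4 items")
    gaps = q[:-1] - q[1:]
    half = n // 2
    top = gaps[: half - 1]  # gaps among the top-half items
    bottom = gaps[n - half :]  # gaps among the bottom-half items
    return float(top.mean() - bottom.mean())
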