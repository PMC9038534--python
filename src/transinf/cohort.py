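"""Synthetic participant cohorts.

Generates participant-level choice datasets with the statistical
structure the fitting and model-comparison machinery expects: cohorts of
simulated learners with heterogeneous parameters, composed of
winner-updating, loser-updating and symmetric subgroups.

Default parameter distributions use the reported subgroup moments where
such moments exist (winner-updaters: alpha_plus mean 0.063 with s.e.m.
0.007 over 64 observers, alpha_minus mean -0.009 with s.e.m. 0.0016;
between-subject s.d. is recovered as s.e.m. * sqrt(n)). Quantities with
no published spread (temperatures, pair-memory rates) use fixed
documented defaults; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import task_env
from .models import DEFAULT_BOUNDS, get_model
from .simulate import simulate_agent

__all__ = [
    "ParamDist",
    "point",
    "gaussian",
    "rectified_gaussian",
    "PROFILES",
    "CohortSpec",
    "ChoiceDataset",
    "generate_cohort",
    "apply_inclusion_filter",
]


@dataclass(frozen=True)
class ParamDist:
    """A per-parameter sampling distribution.

    ``kind`` is "point" or "gaussian"; Gaussian draws are clipped to
    ``(lo, hi)`` when given (a rectified Gaussian when lo = 0).
    """

    kind: str
    mean: float
    sd: float = 0.0
    lo: Optional[float] = None
    hi: Optional[float] = None

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.mean
        x = rng.normal(self.mean, self.sd)
        if self.lo is not None:
            x = max(x, self.lo)
        if self.hi is not None:
            x = min(x, self.hi)
        return float(x)


def point(v: float) -> ParamDist:
    return ParamDist("point", float(v))


def gaussian(mean: float, sd: float, lo=None, hi=None) -> ParamDist:
    return ParamDist("gaussian", float(mean), float(sd), lo, hi)


def rectified_gaussian(mean: float, sd: float, hi=None) -> ParamDist:
    return ParamDist("gaussian", float(mean), float(sd), 0.0, hi)


def _profile(**dists) -> dict:
    base = {
        "eta": gaussian(3.0, 0.5, lo=0.0),
        "tau_item": point(0.04),
        "gamma": point(0.5),
        "tau_pair": point(0.1),
    }
    base.update(dists)
    return base


#: Named subgroup parameter profiles (free parameters are drawn, fixed
#: parameters of the chosen model simply ignore surplus entries).
PROFILES = {
    # one-sided updating of winners; alpha_minus near zero
    "winner_updater": _profile(
        alpha_plus=gaussian(0.063, 0.056, lo=0.0, hi=0.2),
        alpha_minus=rectified_gaussian(0.0, 0.01, hi=0.2),
    ),
    # mirror image: one-sided updating of losers
    "loser_updater": _profile(
        alpha_plus=rectified_gaussian(0.0, 0.01, hi=0.2),
        alpha_minus=gaussian(0.063, 0.056, lo=0.0, hi=0.2),
    ),
    # tied learning rates (alpha duplicated into both rates at draw time)
    "symmetric": _profile(
        alpha=gaussian(0.04, 0.01, lo=0.0, hi=0.2),
    ),
}


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``param_dists`` overrides the per-parameter distributions; otherwise
    each participant draws from the profile assigned by
    ``subgroup_mix`` (fractions over :data:`PROFILES` names, summing to
    1). Subgroup counts are realised deterministically by largest
    remainder, so a given spec always yields the same composition.
    """

    n_participants: int
    design: str = "exp2"
    model: str = "Q2*+P"
    subgroup_mix: dict = field(
        default_factory=lambda: {"winner_updater": 1.0}
    )
    param_dists: Optional[dict] = None
    attribution: str = "winner_loser"

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        total = sum(self.subgroup_mix.values())
        if self.subgroup_mix and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"subgroup fractions must sum to 1, got {total}")
        unknown = set(self.subgroup_mix) - set(PROFILES)
        if unknown:
            raise ValueError(f"unknown subgroup profiles: {sorted(unknown)}")

    def subgroup_counts(self) -> dict:
        names = sorted(self.subgroup_mix)
        raw = {g: self.subgroup_mix[g] * self.n_participants for g in names}
        counts = {g: int(math.floor(raw[g])) for g in names}
        short = self.n_participants - sum(counts.values())
        for g in sorted(names, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
            counts[g] += 1
        return counts


@dataclass
class ChoiceDataset:
    """One participant's session: trial table plus provenance.

    ``trials`` has the environment columns plus ``choice`` (item id) and
    ``correct``. For synthetic data the generating model and parameter
    draws are retained for recovery scoring.
    """

    participant: str
    design_name: str
    trials: pd.DataFrame
    model_name: Optional[str] = None
    params: Optional[dict] = None
    subgroup: Optional[str] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def accuracy(self, mask=None) -> float:
        if mask is None:
            return float(self.trials["correct"].mean())
        return float(self.trials.loc[mask, "correct"].mean())


def draw_params(spec_model, dists: dict, rng: np.random.Generator) -> dict:
    """Draw the model's free parameters from ``dists``.

    Any free parameter without an explicit distribution falls back to
    the midpoint of its fitting bounds.
    """
    spec = get_model(spec_model)
    out = {}
    for name in spec.free_params:
        if name in dists:
            out[name] = dists[name].draw(rng)
        elif name == "alpha" and "alpha_plus" in dists:
            out[name] = dists["alpha_plus"].draw(rng)
        else:
            lo, hi = DEFAULT_BOUNDS[name]
            out[name] = (lo + hi) / 2.0
    return out


def generate_cohort(spec: CohortSpec, seed) -> list:
    """Simulate one dataset per participant.

    The master seed spawns one independent stream per participant
    (covering both the parameter draw and the session simulation), so
    cohorts are reproducible and participants are statistically
    independent.
    """
    design = task_env.get_design(spec.design)
    model = get_model(spec.model)
    counts = spec.subgroup_counts()
    assignment = [g for g in sorted(counts) for _ in range(counts[g])]
    ss = task_env._as_seedseq(seed)
    datasets = []
    for pid, (group, part_ss) in enumerate(
        zip(assignment, ss.spawn(max(spec.n_participants, 1)))
    ):
        draw_ss, sim_ss = part_ss.spawn(2)
        dists = spec.param_dists if spec.param_dists is not None else PROFILES[group]
        values = draw_params(model, dists, np.random.default_rng(draw_ss))
        params = model.make_params(values, attribution=spec.attribution)
        sim = simulate_agent(design, model, params, sim_ss)
        datasets.append(
            ChoiceDataset(
                participant=f"synth{pid:03d}",
                design_name=design.name,
                trials=sim.trials.drop(columns=["cp_hi"]),
                model_name=model.name,
                params=values,
                subgroup=group,
            )
        )
    return datasets


def apply_inclusion_filter(
    cohort: Sequence[ChoiceDataset],
    threshold: float = 0.6,
    last_blocks: int = 2,
) -> tuple:
    """Split a cohort by end-of-session performance.

    Participants whose proportion of correct choices over the final
    ``last_blocks`` blocks falls below ``threshold`` are excluded — the
    standard above-chance learning criterion for this task family.
    Returns ``(included, excluded)`` lists.
    """
    included, excluded = [], []
    for ds in cohort:
        blocks = ds.trials["block"]
        if blocks.nunique() < last_blocks:
            raise ValueError(
                f"{ds.participant}: fewer than {last_blocks} blocks in dataset"
            )
        cut = blocks.max() - last_blocks
        acc = ds.accuracy(blocks > cut)
        (included if acc >= threshold else excluded).append(ds)
    return included, excluded
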