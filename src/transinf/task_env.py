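"""Task environments for pairwise relational learning.

An environment presents a fixed set of ``n_items`` stimuli with a strict
latent rank order (item 1 is the highest-valued, "A"). On every trial two
distinct items are shown and the agent must pick the higher-valued one.
Feedback endorses one of the two items as the winner:

* ``full`` feedback regime: every pair is followed by feedback;
* ``partial``: only neighbouring pairs (rank distance 1) receive feedback,
  so relations between non-neighbours must be inferred transitively.

Feedback can be ``deterministic`` (the truly higher-ranked item always
wins) or ``probabilistic``: each item's momentary value is its rank value
plus independent Gaussian noise, and the item with the larger sample wins.
The noise s.d. is calibrated so that feedback on neighbouring pairs is
truthful at a target rate (0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LatentValueModel",
    "ExperimentDesign",
    "DESIGNS",
    "get_design",
    "calibrate_noise_sd",
    "all_pairs",
    "neighbour_pairs",
    "nonneighbour_pairs",
    "build_trial_sequence",
    "sample_feedback",
    "empirical_truthful_rate",
]

#: Columns of a trial-sequence table, in canonical order.
TRIAL_COLUMNS = [
    "trial",
    "block",
    "item_hi",
    "item_lo",
    "first_position",
    "feedback_scheduled",
    "outcome_winner",
    "truthful",
]


class DesignError(ValueError):
    """Raised for invalid environment configurations."""


def calibrate_noise_sd(target_truthful_rate: float, rank_gap: float = 1.0) -> float:
    """Gaussian noise s.d. giving a target truthful-feedback rate.

    Two items with latent values separated by ``rank_gap`` each receive an
    independent Gaussian perturbation with s.d. ``sigma``. The probability
    that the truly higher item also draws the higher sample is
    ``Phi(rank_gap / (sigma * sqrt(2)))``; inverting gives the closed form

        sigma = rank_gap / (sqrt(2) * Phi^{-1}(target)).

    Parameters
    ----------
    target_truthful_rate
        Desired probability, strictly between 0.5 and 1, that feedback
        endorses the truly higher-ranked item.
    rank_gap
        Latent value difference between the two items (1 for neighbours
        under unit rank spacing).
    """
    if not 0.5 < target_truthful_rate < 1.0:
        raise ValueError(
            f"target_truthful_rate must lie in (0.5, 1), got {target_truthful_rate}"
        )
    if rank_gap <= 0:
        raise ValueError("rank_gap must be positive")
    return rank_gap / (np.sqrt(2.0) * norm.ppf(target_truthful_rate))


@dataclass(frozen=True)
class LatentValueModel:
    """Latent item values plus the per-trial sampling noise.

    ``true_values`` are ordered by item id: index 0 is item 1 ("A"), the
    highest-valued stimulus. ``noise_sd == 0`` makes outcomes
    deterministic.
    """

    true_values: tuple
    noise_sd: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.true_values, dtype=float)
        if v.ndim != 1 or len(v) < 3:
            raise DesignError("need at least 3 ordered item values")
        if not np.all(np.diff(v) < 0):
            raise DesignError("true_values must be strictly decreasing (item 1 highest)")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be non-negative")
        object.__setattr__(self, "true_values", tuple(float(x) for x in v))

    @property
    def n_items(self) -> int:
        return len(self.true_values)

    @property
    def deterministic(self) -> bool:
        return self.noise_sd == 0.0

    def value_gap(self, item_hi: int, item_lo: int) -> float:
        return self.true_values[item_hi - 1] - self.true_values[item_lo - 1]


@dataclass(frozen=True)
class ExperimentDesign:
    """One experimental environment.

    ``neighbour_multiplicity`` / ``nonneighbour_multiplicity`` give how
    often each unordered pair of the corresponding kind appears per block.
    ``truthful_rate`` is the target fraction of truthful feedback on
    neighbour trials under probabilistic feedback; the Gaussian noise is
    calibrated against it for a unit rank gap.
    """

    name: str
    n_blocks: int
    neighbour_multiplicity: int
    nonneighbour_multiplicity: int
    feedback_regime: str  # "full" | "partial"
    feedback_noise: str  # "probabilistic" | "deterministic"
    n_items: int = 8
    truthful_rate: float = 0.8

    def __post_init__(self):
        if self.n_items < 3:
            raise DesignError("n_items must be at least 3")
        if self.neighbour_multiplicity < 1 or self.nonneighbour_multiplicity < 1:
            raise DesignError("pair multiplicities must be >= 1")
        if self.n_blocks < 1:
            raise DesignError("n_blocks must be >= 1")
        if self.feedback_regime not in ("full", "partial"):
            raise DesignError(f"unknown feedback_regime {self.feedback_regime!r}")
        if self.feedback_noise not in ("probabilistic", "deterministic"):
            raise DesignError(f"unknown feedback_noise {self.feedback_noise!r}")
        if (
            self.feedback_regime == "full"
            and self.neighbour_multiplicity != self.nonneighbour_multiplicity
        ):
            raise DesignError(
                "full-feedback designs present all pairs equally often"
            )
        if self.feedback_noise == "probabilistic" and not 0.5 < self.truthful_rate < 1:
            raise DesignError("truthful_rate must lie in (0.5, 1)")

    # -- combinatorics ----------------------------------------------------
    @property
    def n_neighbour_pairs(self) -> int:
        return self.n_items - 1

    @property
    def n_nonneighbour_pairs(self) -> int:
        n = self.n_items
        return n * (n - 1) // 2 - (n - 1)

    @property
    def trials_per_block(self) -> int:
        return (
            self.n_neighbour_pairs * self.neighbour_multiplicity
            + self.n_nonneighbour_pairs * self.nonneighbour_multiplicity
        )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def latent_model(self) -> LatentValueModel:
        """Unit-spaced latent values with calibrated noise."""
        values = tuple(float(self.n_items - i) for i in range(self.n_items))
        if self.feedback_noise == "deterministic":
            sd = 0.0
        else:
            sd = calibrate_noise_sd(self.truthful_rate, rank_gap=1.0)
        return LatentValueModel(values, sd)


#: Named design presets. exp1 presents all 56 ordered pairings per block,
#: i.e. every unordered pair twice with randomised member order (8 x 56 =
#: 448 trials). exp3 replicates the exp2 schedule (the original studies
#: differed only in display modality, which is not modelled);
#: ``partial_uniform`` is the baseline simulation environment: the exp1
#: schedule with partial, deterministic feedback.
DESIGNS = {
    "exp1": ExperimentDesign("exp1", 8, 2, 2, "full", "probabilistic"),
    "exp2": ExperimentDesign("exp2", 8, 5, 2, "partial", "probabilistic"),
    "exp3": ExperimentDesign("exp3", 8, 5, 2, "partial", "probabilistic"),
    "exp4": ExperimentDesign("exp4", 6, 4, 2, "partial", "deterministic"),
    "partial_uniform": ExperimentDesign(
        "partial_uniform", 8, 2, 2, "partial", "deterministic"
    ),
}


def get_design(name_or_design) -> ExperimentDesign:
    if isinstance(name_or_design, ExperimentDesign):
        return name_or_design
    try:
        return DESIGNS[name_or_design]
    except KeyError:
        raise DesignError(
            f"unknown design {name_or_design!r}; available: {sorted(DESIGNS)}"
        ) from None


def all_pairs(n_items: int) -> list:
    """All unordered pairs as (item_hi, item_lo), item_hi higher-valued."""
    return [(a, b) for a in range(1, n_items) for b in range(a + 1, n_items + 1)]


def neighbour_pairs(n_items: int) -> list:
    return [(a, a + 1) for a in range(1, n_items)]


def nonneighbour_pairs(n_items: int) -> list:
    return [(a, b) for (a, b) in all_pairs(n_items) if b - a > 1]


def sample_feedback(
    pair: tuple,
    latent: LatentValueModel,
    rng: np.random.Generator,
) -> tuple:
    """Draw the feedback-endorsed winner for one eligible pair.

    Deterministic latent model: the truly higher item always wins.
    Probabilistic: each item's value is perturbed by independent Gaussian
    noise and the larger sample wins.

    Returns ``(outcome_winner, truthful)`` where ``truthful`` flags that
    the winner is the truly higher-ranked item.
    """
    hi, lo = pair
    if hi == lo:
        raise ValueError("pair items must differ")
    if hi > lo:
        hi, lo = lo, hi  # item ids ascend with decreasing value
    if latent.deterministic:
        return hi, True
    x_hi = latent.true_values[hi - 1] + rng.normal(0.0, latent.noise_sd)
    x_lo = latent.true_values[lo - 1] + rng.normal(0.0, latent.noise_sd)
    if x_hi >= x_lo:
        return hi, True
    return lo, False


def empirical_truthful_rate(
    latent: LatentValueModel, pair: tuple, n_draws: int, seed
) -> float:
    """Monte-Carlo fraction of truthful outcomes for one pair (vectorised)."""
    hi, lo = min(pair), max(pair)
    rng = np.random.default_rng(seed)
    gap = latent.value_gap(hi, lo)
    if latent.deterministic:
        return 1.0
    diff = gap + rng.normal(0.0, latent.noise_sd, n_draws) - rng.normal(
        0.0, latent.noise_sd, n_draws
    )
    return float(np.mean(diff >= 0))


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def build_trial_sequence(design, seed) -> pd.DataFrame:
    """Generate the full trial table for one session.

    Each block contains every unordered pair exactly at its multiplicity;
    order within a block and the presentation order of the two pair
    members are uniformly random. Feedback outcomes are pre-sampled from
    the latent value model for every feedback-scheduled trial (outcomes in
    this task depend on the environment, not on the agent's choice).

    The master seed is split into independent sub-streams for trial order
    and feedback sampling, so the same schedule can be replayed with fresh
    feedback noise and vice versa.

    Returns a DataFrame with columns ``trial, block, item_hi, item_lo,
    first_position, feedback_scheduled, outcome_winner, truthful``.
    ``item_hi`` is the truly higher-valued item; ``first_position`` is
    "hi" or "lo" depending on which member was presented first.
    ``outcome_winner`` is pd.NA on no-feedback trials.
    """
    design = get_design(design)
    ss = _as_seedseq(seed)
    seq_ss, fb_ss = ss.spawn(2)
    rng_seq = np.random.default_rng(seq_ss)
    rng_fb = np.random.default_rng(fb_ss)
    latent = design.latent_model()

    block_pairs: list = []
    for pair in neighbour_pairs(design.n_items):
        block_pairs.extend([pair] * design.neighbour_multiplicity)
    for pair in nonneighbour_pairs(design.n_items):
        block_pairs.extend([pair] * design.nonneighbour_multiplicity)
    block_pairs = np.array(block_pairs)  # (trials_per_block, 2)

    rows = []
    trial = 0
    for block in range(1, design.n_blocks + 1):
        order = rng_seq.permutation(len(block_pairs))
        for hi, lo in block_pairs[order]:
            trial += 1
            hi, lo = int(hi), int(lo)
            first = "hi" if rng_seq.random() < 0.5 else "lo"
            scheduled = design.feedback_regime == "full" or (lo - hi) == 1
            if scheduled:
                winner, truthful = sample_feedback((hi, lo), latent, rng_fb)
            else:
                winner, truthful = pd.NA, pd.NA
            rows.append(
                (trial, block, hi, lo, first, scheduled, winner, truthful)
            )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["outcome_winner"] = df["outcome_winner"].astype("Int64")
    df["truthful"] = df["truthful"].astype("boolean")
    return df
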