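# Methods

This note documents the modelling assumptions, parameter conventions,
numerical choices and known limitations of `transinf`.

## Task environments

Eight items (ids 1..8, 1 = "A", highest-valued) carry unit-spaced latent
values. A session consists of blocks in which every unordered pair
appears exactly at its design multiplicity, shuffled within block, with
the two pair members in random presentation order. Presets:

| design | blocks | neighbour × | non-neighbour × | trials | feedback |
|---|---|---|---|---|---|
| `exp1` | 8 | 2 | 2 | 448 | full, probabilistic |
| `exp2` / `exp3` | 8 | 5 | 2 | 616 | partial, probabilistic |
| `exp4` | 6 | 4 | 2 | 420 | partial, deterministic |
| `partial_uniform` | 8 | 2 | 2 | 448 | partial, deterministic |

`exp1` realises "all 56 ordered pairings per block" as multiplicity 2
per unordered pair with randomised member order. `exp2` presents
neighbour pairs 2.5× as often as non-neighbours, `exp4` 2×.
`partial_uniform` is the baseline environment for the performance
simulations: the exact schedule of those simulations is not pinned down
anywhere, so the package uses the `exp1` slot structure with partial,
deterministic feedback, treating neighbour oversampling and
probabilistic outcomes as robustness variants (they do not change the
qualitative sweep conclusions; see the invariants tests).

**Probabilistic feedback.** Each item's momentary value is its rank
value plus independent Gaussian noise; the larger sample wins. The
noise s.d. is calibrated in closed form, σ = gap / (√2 Φ⁻¹(target)),
so that neighbour feedback is truthful at exactly the target rate
(default 0.80, σ ≈ 0.8402 for unit gaps). The calibration is enforced
per unit rank gap, so more distant pairs are automatically more
truthful — a property of the generative assumption, not a separate
design knob. Feedback outcomes are pre-sampled with the trial sequence:
in this task the endorsed winner depends on the environment, never on
the agent's response.

**Seeding.** Every public entry point takes one master seed, split via
`numpy.random.SeedSequence.spawn` into independent streams (trial
order, feedback sampling, choice sampling, parameter draws, optimiser),
so each randomness source is separately reproducible and cohort members
are independent.

## Model family

The model space is the nested family described in the README: item-level
Q-learning (plain or difference-weighted, symmetric or asymmetric),
pair-level beta memory (with or without chained inference), and their
arbitration mixtures. Conventions that required a decision:

- **Pair-level choice rule is centred.** The logistic is applied to
  (p − 0.5)/τ_pair rather than p/τ_pair. An uncentred rule would map
  indifference (p = 0.5) to a choice probability above 0.5 and break
  the arbitration rule's premise that preference strength is deviation
  from 0.5. With the centred form, indifference yields chance.
- **Arbitration ties go to the item level.** The strength comparison is
  stated with strict inequalities only; a fixed deterministic tie rule
  keeps likelihoods well defined. Ties are measure-zero for continuous
  parameters, and in the pure-model limits the rule is inert: with
  γ = 0 the pair system never deviates from 0.5 (the mixture equals the
  pure Q model), and with α = 0 the item system never does (pure P/Pi).
- **"Winner" means the feedback-endorsed item**, which on untruthful
  probabilistic trials is the truly lower item: agents observe feedback,
  not latent truth. Correctness, in contrast, is always scored against
  true ranks.
- **Chosen/unchosen attribution variant.** The alternative updating
  scheme applies α⁺ to the chosen and α⁻ to the unchosen item while the
  update targets (+1-like for the winner, −1-like for the loser) still
  follow the outcome. Whether sign structure follows choice or outcome
  is ambiguous in prose; outcome-following is implemented, as the
  variant is explicitly a re-attribution of learning *rates*.
- **Pair memory holds neighbour pairs only** (they alone receive a
  direct feedback signal under partial feedback); non-feedback trials
  trigger no update of any kind. Beta counts start at U = L = 1, the
  uniform prior, giving every initial preference 0.5; Q-values start
  at 0, so the first choice is always a coin flip.
- **P variants pin λ = 100** (the fitting upper bound): at that value
  1/d^(λ+1) underflows to zero for every rank distance ≥ 2, which
  disables chained inference exactly rather than approximately.

## Parameters and bounds

| parameter | meaning | fitting bounds | default/simulation value |
|---|---|---|---|
| α, α⁺, α⁻ | learning rates (winner/loser) | [0, 0.2] (±0.2 in negative-rate mode) | sweep grid 0–0.1 |
| η | difference-weighting scale | [0, 10] | 8 (simulations), ~3 (cohorts) |
| τ_item | item-level temperature | [0.01, 1] | 0.2 full / 0.04 partial feedback |
| γ | pair-memory learning rate | [0, 1] | 0.5 |
| λ | retrieval-failure exponent | [0, 100] | 100 (P), ~1 (Pi cohorts) |
| τ_pair | pair-level temperature | [0.01, 1] | 0.1 |

The temperature boxes are nominally open at 0; 0.01 is a numerical
floor keeping the logistic finite. Choice probabilities are clipped to
[1e−9, 1 − 1e−9] before logs. Q-values stay bounded (|Q| ≤ 2) whenever
α(1 + 2η) ≤ 2, which covers all default settings; outside that regime
the difference-weighted map is an expansion and diverges — the sweep
grids never enter it.

## Fitting

Negative log-likelihood replays a session sequentially: each trial's
choice probability comes from the state before that trial's update, and
recorded feedback is applied verbatim; all trials (including
no-feedback trials) contribute to the likelihood. Minimisation uses
differential evolution (best/1/bin, population 15 per free dimension,
200 generations by default, uniform box prior, seeded) followed by a
bounded L-BFGS-B polish whose forward-difference gradient is evaluated
in a single vectorised likelihood call per step. The likelihood kernel
is numba-compiled and evaluates the whole DE population per generation
in one call, which is what makes the recovery studies desk-feasible.

BIC = k ln N + 2 NLL with N = all modelled trials (whether N should
count feedback trials only is ambiguous; all-trials is used, matching
the all-trials likelihood). The null model for pseudo-R² = 1 −
BIC_model/BIC_null guesses (CP = 0.5) with zero free parameters, so
BIC_null = 2 N ln 2 and R² = 0 is exactly chance. The asymmetry index
A = (α⁺ − α⁻)/|α⁺ + α⁻| lies in [−1, 1] for non-negative rates; with
the negative-rate fitting mode it can exceed that range, and it is
reported as NaN when the rates cancel.

## Group-level comparison (pxp)

Random-effects model selection from per-participant log-evidences
(approximated as −BIC/2): a variational Dirichlet posterior over
population model frequencies (uniform prior), exceedance probabilities
by 10⁶ Dirichlet samples, protected by the Bayesian omnibus risk,
pxp = (1 − BOR)·xp + BOR/K. The implementation is from scratch (no
installed package provides it) and is checked against structural
oracles: symmetry under identical evidences, invariance to
per-participant evidence shifts, and near-unit pxp for a dominant
model.

## Synthetic cohorts and recovery studies

Cohort subgroups (winner-updaters, loser-updaters, symmetric learners)
draw parameters from documented distributions. Where published moments
exist they are used: winner-updaters draw α⁺ from a Gaussian with mean
0.063 (between-subject s.d. recovered from the reported s.e.m. over 64
observers) and α⁻ from a rectified Gaussian (µ = 0, σ = 0.01);
η ~ N(3, 0.5). Temperatures and γ have no published spread and use
fixed defaults (τ_item = 0.04 partial / 0.2 full, γ = 0.5,
τ_pair = 0.1) — acknowledged inventions, chosen to reproduce realistic
accuracy levels (~0.7–0.8 overall with clearly above-chance
non-neighbour performance, the empirically observed range).

**Parameter recovery** varies each free parameter of Q2\*+P over 20
evenly spaced interior values of its fitting bounds (others at a fixed
winner-updating base), simulates 3 sessions per value on the `exp2`
design, refits, and correlates generative with recovered values (60
points per correlation; ~360 fits). The grid uses bin midpoints: at a
boundary such as γ = 0 the varied parameter drops out of the generative
model and its recovered value is arbitrary, so endpoint grids
contaminate the correlation with pure noise. The weakest-recovered
parameter is γ, which trades off against τ_pair along a likelihood
ridge (the asymptotic neighbour preference saturates in γ); this is a
genuine identifiability limit of the design, not an optimiser artefact:
the learning rates and η recover at 0.84–0.99 while the γ and τ_pair
self-correlations land around 0.55–0.65, varying with the seed.
Recovery fits use differential evolution at a tight tolerance
(`RECOVERY_FIT_SETTINGS`), at which refitting the same dataset from
different optimiser seeds reproduces the likelihood to ~10⁻³ nats.

**Model recovery** simulates datasets from each of the eight family
models (winner-biased generative regimes, where the family is most
distinguishable under partial feedback), refits all models, and tabulates
best-BIC counts into p(fit|gen), inverted by Bayes's rule under a uniform
prior into p(gen|fit). Desk scale is 4 runs per model; residual
confusions are the expected nesting ones (Pi variants occasionally won
by their P counterparts when the drawn λ is large).

## Scale choices

Default desk scales: sweeps use an 11×11 grid over [0, 0.1] with 20
replications (the reference grid, 101×101 in 0.001 steps, is available
via `default_sweep_grid()`); compression and learning-curve cohorts use
100 agents; recovery uses the counts above. Sweeps evaluate all grid
cells on shared trial sequences within a replication (common random
numbers), which removes between-cell sequence variance from the
comparison; each replication uses a fresh sequence.

## Pair-category partition

Learning-curve categories split the 21 non-neighbour pairs into three
equal terciles by the mean rank of the pair members. The partition is
made *mirror-equivariant* (the low bin is the exact mirror image of the
high bin under i → 9−i, with mirrored distance-descending tie-breaks):
a naive one-ended tie-break produces low/high bins that are not mirror
images and thereby a spurious low>high accuracy difference of ~0.016
even for perfectly symmetric learners — large enough to contaminate the
value-compression contrast. With the equivariant partition, symmetric
full-feedback learners show a low−high difference of exactly zero in
expectation, so the observed low>high ordering under one-sided partial-
feedback learning is attributable to the learning policy alone.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses assume:
block-exact pair schedules, calibrated feedback noise, heterogeneous
learner subgroups, binomial choices from the model family itself. It
does not emulate human lapses, reaction-time structure, attention
drift, practice effects or any departure from the fitted model class —
so passing recovery here demonstrates identifiability of the procedure,
not correctness of the model family for real behaviour. Conclusions
about human data additionally rest on the model-comparison machinery,
which is exercised against structural oracles only.

## Known limitations

- Hierarchical/Bayesian parameter estimation and parameter standard
  errors are out of scope; fits are per-participant maximum likelihood.
- The γ/τ_pair ridge limits pair-memory parameter recovery (minimum
  self-correlations around 0.55–0.65 at the documented scale, varying
  by seed).
- The value-transfer and Elo-style comparison models, and the
  confirmation-bias extension, are not implemented.
- Display-level differences between the two partial-feedback
  probabilistic designs are not modelled; `exp3` aliases the `exp2`
  schedule.
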