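# Methods

## Task model

The environment is a probabilistic Go/NoGo reversal task. Each block
draws two tactile patterns without replacement from a set of eight and
pairs them with the two responses; within a block the latent mapping
(stimulus1→Go / stimulus2→NoGo, coded 1, versus its reverse, coded 0)
is fixed until a reversal trial drawn uniformly from an inclusive
window (default trials 20–25, 1-based), after which it flips. The
reversal trial is defined as the *first* trial governed by the reversed
contingency. Reward is pre-drawn per trial: the currently-correct
response is rewarded with probability `p_high` (default 0.7), the other
response otherwise; exact per-block reward counts are not balanced
(independent Bernoulli draws). The stimulus sequence is a random
permutation of a near-balanced multiset (⌈n/2⌉ / ⌊n/2⌋ of each
pattern). Defaults: 3 runs × 4 blocks × 45 trials = 540 trials.

Because reward assignment precedes the response, the binary evidence
variable u₁ ("does this trial's feedback support mapping 1?") is a
property of the design alone: whichever response the agent makes, a
trial either rewards the mapping-1-consistent response or punishes it.
`design_input_sequence` exposes this stream; it is the input both to
the Bayes-optimal parameter search and (implicitly) to every simulated
agent.

Trials are labelled into four phases of `phase_len` (default 10)
trials: LN = trials 1..10, LE = the 10 trials ending just before the
reversal, RN = the first 10 reversed trials, RE = the last 10 trials of
the block. When the reversal falls on trial 20 the LN and LE windows
overlap on trial 10; the later label (LE) wins, so LN holds 9 trials in
that one configuration. Phase labels drive the phase-accuracy summaries
and define the RSA epochs.

RNG discipline: a master `SeedSequence` spawns one child stream per
block (and, in cohort simulation, per subject), so enlarging the design
never perturbs earlier blocks.

## Behavioral models

All four agents choose between the two latent mappings; the motor
response then follows deterministically from the chosen mapping and the
presented stimulus. Perceptual state resets at each block boundary
(each block introduces novel patterns); parameters are shared across
blocks. Whether beliefs should instead persist across blocks is a
genuine modelling choice — we reset, because the stimulus pair is new
and the initial contingency is re-randomized per block.

1. **Random responding.** p(y=1) = b, b ∈ [0,1]. One parameter.
2. **Noisy win-stay-lose-switch.** With lapse ε ∈ [0,1], the agent
   repeats its previous mapping choice with probability 1 − ε/2 after a
   reward and ε/2 after a non-reward; the first trial of each block is
   uniform.
3. **Rescorla–Wagner.** Two option values (one per mapping) start at
   V₀ = 0.5; only the chosen option is updated,
   V ← V + α(r − V) with r ∈ {0,1}; choices are softmax with inverse
   temperature β ≥ 0.
4. **Two-level HGF.** State u₂ (log-odds of mapping 1) with prediction
   û₁ = s(u₂), Bernoulli prediction variance φ̂₁ = û₁(1−û₁), predicted
   level-2 variance φ̂₂ = φ₂ + e^ω, posterior weight
   φ₂ = 1/(1/φ̂₂ + φ̂₁), prediction error δ₁ = u₁ − û₁, update
   u₂ ← u₂ + φ₂δ₁. The third level is removed by fixing the volatility
   constants to zero, appropriate for a task whose volatility is
   announced (one reversal per block). Initial values u₂₀ = 0,
   φ₂₀ = 1 (configurable; they are not stated anywhere authoritative).
   The prediction variance is evaluated at the *current* trial's
   prediction û₁(t) = s(u₂(t−1)); since û₁(t) is itself a function of
   the t−1 posterior, this is the internally consistent reading of the
   update equations. The response model is the unit-square sigmoid
   p(y=1) = û₁^ζ / (û₁^ζ + (1−û₁)^ζ) with determinism ζ ≥ 0 — the only
   normalizing form of that sigmoid (ζ=0: indifference; ζ=1:
   probability matching; ζ→∞: greedy).

The unsigned prediction error |δ₁| (Bayesian surprise) is carried in
every HGF trajectory, as it is the quantity of interest for
neuroimaging regressors.

Simulation defaults for the four-model comparison cohort: b = 0.5,
ε = 0.05, β = 5, ζ = 0.5, with the perceptual parameters (α for RW, ω
for HGF) set to their Bayes-optimal values for the design's evidence
stream.

## Bayes-optimal perceptual parameters

For a fixed binary input stream (per-block reset), the Bayes-optimal
parameter minimizes cumulative Shannon surprise
Σ_t −log p(u₁(t) | prediction). For the HGF the prediction is û₁(t);
for RW a single tracked probability V (V₀ = 0.5) updated by the delta
rule. Bounded scalar optimization (Brent) over ω ∈ [−12, 3] and
α ∈ [0.001, 0.999]; a flat objective (e.g. an empty input) returns the
interval midpoint with a warning. For the default design the optima
land near ω* ≈ −3 and α* ≈ 0.1.

## Fitting and evidence

MAP estimation maximizes log-likelihood + log-prior on transformed
scales: identity for ω, log for ζ and β, logit for α, b and ε. Priors
(weakly informative, centered near the simulation regime; the
originally used values are not available): ω ~ N(−3, 16),
log ζ ~ N(0, 1), logit α ~ N(0, 1), log β ~ N(ln 5, 1),
logit b, logit ε ~ N(0, 1). Optimization is BFGS from `n_restarts`
(default 8; 3–4 in the test suites) prior-drawn initializations; the
best finite optimum wins. A zero-probability observed response yields
an infinite NLL with a warning rather than an exception, so the line
search can back off.

Log-model evidence uses the Laplace approximation
LME = log-joint(θ̂) + (d/2)·log 2π − ½·log det H, with H the central
finite-difference Hessian (step 1e−4, full stencil) of the negative
log-joint on the transformed scale. A non-positive-definite H is
repaired by clipping eigenvalues at 1e−8 (with a warning); a Hessian
that is still singular raises. On a one-parameter Bernoulli model the
Laplace value agrees with direct quadrature to well under 0.01 nats.
BIC = 2·NLL + d·ln n (smaller is better). Cross-validation is
leave-one-run-out: fit on the remaining runs, score the mean held-out
log predictive probability, average over folds.

## Random-effects model selection

Per-subject LME differences are log Bayes factors. Random-effects BMS
uses the variational Dirichlet scheme: responsibilities
u_nk ∝ exp(LME_nk + ψ(α_k) − ψ(Σα)) and concentration updates
α_k = α₀ + Σ_n u_nk, iterated until max|Δα| < 1e−6 (α₀ = 1 uniform
prior). Expected frequencies are α/Σα; exceedance probabilities are
estimated from Dirichlet(α) Monte-Carlo draws (default 10⁶, seeded;
argmax ties broken toward the first index — a measure-zero event). The
MC error on an exceedance probability is ≲ 3/√n_draws.

A practical note from the recovery studies: on data generated by the
*random* agent, comparing only RW and HGF still "selects" one of them —
selection pressure comes entirely from prior/curvature geometry when
both models sit at chance. The meaningful null control is to include
the random-responding model itself, which then wins in the majority of
coin-flip subjects while HGF wins on HGF-generated data.

## Behavioral summaries

p(staying) is the probability of repeating the previous *mapping
choice* y (not the motor response), conditioned on the previous trial's
outcome, excluding the first trial of each block; an empty conditional
is NaN, never 0. "Correct" in accuracy summaries means the response
matching the currently-contingent higher-reward option, not the
realized reward — the reading under which a perfect agent scores 1.0
rather than 0.7. Reversal-aligned curves average per-block accuracy
indicator sequences at each offset from the reversal trial (offset 0 =
first reversed trial); offsets outside a block are dropped from that
block with a warning when a whole offset is empty. Phase contrasts are
two-sided paired t-tests on per-subject phase accuracies.

## Cross-phase RSA

Empirical RDMs are 4×4 Pearson-correlation matrices between pre-epoch
(LE) and post-epoch (RN or RE) condition patterns over HIT/CR/FA/MISS;
rows and columns index different epochs, so no symmetry exists or is
enforced. Constant pattern vectors are rejected by name (Pearson is
undefined). The model RDMs are binary: outcome-selective = the
diagonal; stimulus-selective = {(HIT,CR), (CR,HIT), (FA,MISS),
(MISS,FA)} — the pairs that share a tactile pattern once the mapping
has flipped. The two similar sets are disjoint.

The summary statistic is the mean correlation over model-similar cells
minus the mean over model-dissimilar cells (computed on r; the 1−r
distance framing differs only by sign). Group inference: (1) one-sided
Wilcoxon signed-rank across subjects for a positive median; (2) a
one-sided permutation test whose null re-draws, in each of n_perm
(default 10,000) iterations, an independent permutation of the pre
(row) and post (column) condition labels of every subject's RDM and
recomputes the group mean; p = (b+1)/(n_perm+1). Condition-level
permutation is used because the RDM itself is condition-wise;
trial-level shuffling before averaging would require trial-wise
patterns, which this pipeline does not model. The reported "effect
size" is the observed group-mean statistic.

## Synthetic pattern generator

Each subject receives standard-normal voxel templates: one per tactile
pattern (stimulus coding; the pattern carried by each outcome category
flips across the reversal) and one per outcome category (outcome
coding; epoch-invariant). A condition vector is
`stim_signal·stimulus_template + outcome_signal·outcome_template +
N(0, noise_sd²)` per voxel. By construction the stimulus signal raises
exactly the stimulus-model-similar correlations and the outcome signal
exactly the diagonal, so selectivity recovery is well-posed: at
signal-to-noise 1 with 32 subjects and 100 voxels, the coded model is
significant and the other is not (its statistic is in fact negative,
because the coded signal lives entirely in the other model's
"dissimilar" cells).

What the generator does *not* emulate: spatial voxel correlations,
haemodynamic or temporal autocorrelation structure, condition-count
imbalance between epochs, between-subject template similarity, and any
coupling between behavioral performance and pattern strength. Passing
RSA tests therefore demonstrate the statistical machinery is calibrated
and sensitive under idealized coding, not that real BOLD patterns
behave this way.

## Problem sizes and numerical choices in the shipped studies

- Model/parameter recovery: 20 subjects × 540 trials, generating
  parameters ω ~ N(−3, 1) and ζ ~ LogNormal(ln 1.5, 0.5²) — enough
  spread for rank correlation, centered on the Bayes-optimal regime;
  4 optimizer restarts. The short-length comparison refits on the
  first run (135 trials).
- Random-control cohort: 10–12 coin-flip subjects fit by Random and
  HGF; 3 restarts.
- p(staying) fingerprints: 1000 simulated experiments per model on one
  fixed design.
- RSA calibration: 200 null datasets of 8 subjects × 50 voxels at
  n_perm = 200, Kolmogorov–Smirnov uniformity check at α = 0.01;
  selectivity recovery at 32 subjects × 100 voxels, n_perm = 1000
  (tests) or 10,000 (acceptance script).
- Exceedance draws: 10⁶ in the acceptance script's recovery study,
  2×10⁵ elsewhere.

## Known limitations

- Two-level binary HGF only; no volatility (third-level) learning, no
  continuous inputs, no reaction-time model.
- Invalid/late trials are never simulated; the `valid` flag exists for
  imported real data and is honored by the likelihood.
- The Laplace evidence assumes a locally Gaussian posterior; for
  near-boundary MAP estimates (e.g. ζ̂ → 0 on random responders) the
  eigenvalue repair makes the value usable but approximate.
- The RSA permutation scheme fixes the per-subject RDM and permutes
  labels; it does not propagate pattern-estimation noise from the
  (absent) GLM stage.
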