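# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `gazecontext` package.

## Task and stimulus design

The modelled task is a three-alternative risky choice: each trial shows three
all-or-nothing gambles, each a probability `p` (percent) to win an amount `m`
(EUR, minimum 1). Sessions consist of three block pairs. In each estimation
block a simulated prospect-theory agent answers up to 30 binary choices in
three interleaved one-up/one-down staircases, calibrating outcomes so that
four gambles C_B, B, A, C_A with `p` = 55/65/75/85 % are approximately equally
preferred (B is fixed at 65 %, 15 EUR). The staircase step starts at 2 EUR,
halves at each preference reversal, and floors at 0.25 EUR; these step rules
are this package's choice — only the up/down adjustment rule is given by the
design. Because C_A is calibrated against the *current* A estimate, its value
carries extra estimation error, as in the original procedure. At block end the
estimates are projected onto the feasible set (outcomes decreasing in `p` with
neighbouring gaps ≥ 2 EUR). Dominated decoys are constructed exactly
2 percentage points and 1 EUR below A and B.

Each experimental block holds 75 trials: 16 per decoy set {A,B,C_A},
{A,B,C_B}, {A,B,D_A}, {A,B,D_B} and 11 distractor trials whose options have
expected value 10 EUR with `p` drawn from low/medium/high bands. Per trial,
attribute noise (±3 % on `p`, −1/0 EUR on `m`) is added; dominated decoys
receive the identical draw as their target, so dominance survives. Screen
positions are randomised per trial; the vertical arrangement of `p` and `m`
inside a gamble is a display property with no consumer in any analysis and is
not represented.

## Gaze generator

Fixations follow a first-order Markov chain over the six alternative ×
attribute AOIs. With probability `p_within` (default 0.55) the next fixation
switches attribute within the current alternative; otherwise it jumps to
another alternative with selection weights `1 + target_bias·[target] +
p_return·[previous alternative]`. Durations are 80 ms (the detection
threshold) plus a gamma(2, 90 ms) draw; the sequence ends after each fixation
with probability `stop_prob` = 0.08, so response time emerges as the summed
duration (mean ≈ 12.6 fixations, ≈ 3.3 s). The default `target_bias` = 0.15
produces a mean relative-dwell advantage of targets over competitors of about
0.011–0.018, the order of magnitude reported empirically (≈ 0.014–0.022).

What the generator does *not* emulate: value-driven gaze (looking longer at
higher-valued options), systematic within-trial dynamics (early exploration
vs. late confirmation), and the empirical pattern that longer decoy dwell
predicts *more* target choices in attraction trials. In the Markov process
decoy dwell simply crowds out target dwell, so GLA-simulated data show a
negative decoy-dwell median-split effect where humans show a positive one.
Passing tests therefore certify the pipeline's internal consistency, not that
real gaze has this structure.

Cleaning re-codes non-AOI fixation runs flanked by the same AOI to that AOI,
discards runs flanked by different AOIs, and discards leading/trailing
non-AOI fixations (the boundary rule is this package's choice).

## Choice models

All models output a trinomial via a soft-max with inverse temperature β over
final preference values.

* **Random**: uniform 1/3; the nested baseline (β = 0 in any other model).
* **PT**: x_i = w(p_i)·U(m_i) with U(m) = m^α and
  w(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ}, γ ∈ [0.28, 1] (below ≈ 0.28 the
  weighting function loses monotonicity). Gaze-independent.
* **GLA** (gaze-dependent leaky accumulator):
  X_i(n) = (1−λ)·X_i(n−1) + θ_i(n)·x_i with θ_i(n) = 1 if alternative i is
  fixated at fixation n, else θ ∈ [0, 1]; λ ∈ [0, 1] is the leak
  (loss convention). Fixating either attribute cell counts as fixating the
  alternative. Default resolution is one step per fixation; the duration
  variant takes round(duration/10 ms) steps (min 1) per fixation. Empty
  sequences yield uniform probabilities with a warning.
* **GB_dyn**: same accumulation with x ≡ 1 (fixation counts, leaky);
  **GB_stat**: soft-max over total dwell in seconds. Both ignore attributes.
* **MDFT**: attributes are log-transformed and min–max rescaled to [0, 1]
  over the *whole dataset being fit* (per-trial rescaling would erase the
  compromise decoys' extremity). Valences V(t) = C·M·W(t) + ε(t) with the
  contrast matrix C (diag 1, off-diag −1/2), one-hot attribute attention
  W(t) (P(probability) = w) and iid N(0, σ²) noise per alternative applied
  after the contrast. Preferences P(t) = S·P(t−1) + V(t) with
  S = I − φ₂·exp(−φ₁·D) applied elementwise; D holds squared pairwise
  distances in indifference/dominance coordinates,
  D_ij = ΔI² + w_d·ΔD², ΔI = (Δa₁−Δa₂)/√2, ΔD = (Δa₁+Δa₂)/√2. When the
  spectral radius of S is < 1 the stationary state is treated as normal with
  ξ = (I−S)^{-1}μ and Ω solving Ω = SΩSᵀ + Φ; choice probabilities are
  Thurstone probabilities P(P_i > P_j, P_i > P_k) from the bivariate normal
  of the two contrasts. Unstable parameter points give likelihood −∞ so the
  optimizer routes around them; trials with three identical alternatives
  (exactly on the stability boundary) return uniform by symmetry.

  The stationary normality is a central-limit approximation of the one-hot
  attention process: exact for the mean and covariance, approximate for the
  argmax probabilities. The approximation error vanishes as σ grows (per-step
  noise dominates) and can reach a few percentage points when σ is small
  relative to the contrast magnitudes (~0.03 at σ ≈ 0.3 on this design);
  the simulator-vs-analytic checks therefore sample σ ∈ [1, 3].

Fitting bounds: α ∈ (0, 3], γ ∈ [0.28, 1], β ∈ [0, 100], λ, θ ∈ [0, 1];
MDFT w ∈ [0, 1], φ₁ ∈ [0, 10], φ₂ ∈ [0, 1], w_d ∈ [1, 50], σ ∈ (0, 10].
The α/β boxes are generous defaults (the originals are unpublished) recorded
in the run configuration.

## Switchboard

The six switches (attribute integration, evidence comparison,
alternative-wise and attribute-wise gaze discount, leak, inhibition)
combine into 192 variants of X(t) = S·X(t−1) + C·(Θ ⊙ x). Two conventions
matter:

* **Leak parameter**: the switchboard's λ is *retention* (1 = perfect
  memory); the GLA's λ is *loss*. The mapping retention = 1 − loss is applied
  explicitly (`gla_params_to_variant`) to prevent silent sign errors.
* **Contrast placement**: the contrast is applied to the gaze-discounted
  inputs, C·(Θ⊙x). Under this order — and only under it — comparative and
  independent accumulation give identical soft-max probabilities whenever
  leak and inhibition are uniform across alternatives (C then commutes with
  S, and C·v = 3/2·v + shift is absorbed by the free β), which is exactly the
  identifiability collapse from 192 to 160 classes. The collapse is verified
  numerically for all 32 merged pairs.

Attribute-wise discount η scales the unattended attribute dimension of *all*
alternatives — before weighting/utility under multiplicative integration,
after divisive normalization under additive integration. Distance-dependent
inhibition reuses the MDFT preprocessing and sets off-diagonals to
−ϕ·exp(−ϕ·D_ij), with the attribute weighting w_p entering the distance as
(2w_p·Δa_p, 2(1−w_p)·Δa_m); the single ϕ plays magnitude and sensitivity, an
interpretation choice since the original parameterisation of this switch is
underdetermined (see the module docstring). Gaze-dependent inhibition sets
the fixated alternative's column to −ϕ; gaze-dependent leak spares the
fixated alternative's diagonal.

## Fitting and model comparison

Parameters are estimated per participant by minimising the summed negative
log-likelihood over *all* trials (attraction, compromise, distractor) with
scipy's differential evolution (Latin-hypercube init, population
popsize × dim, deferred updating, polish; seeded). Probabilities are floored
at 1e-12 before the log. Any fit ending worse than the nested random model
(negLL = n·ln 3, reachable at β = 0) is replaced by the random model's
likelihood and flagged as a non-converged fallback; the variant's parameter
count is kept for BIC = 2·negLL + k·ln n.

Group comparison approximates each participant × model log evidence as
−BIC/2 and runs random-effects Bayesian model selection: a variational
Dirichlet posterior over model frequencies, exceedance probabilities by
Monte-Carlo argmax sampling of that Dirichlet (200 000 draws, seeded), and
protection by the Bayes omnibus risk BOR = 1/(1+exp(F₁−F₀)), where F₁ is the
variational free energy and F₀ the evidence of the equal-frequency null:
pXP = (1−BOR)·XP + BOR/K. Identical evidence yields pXP = 1/K exactly;
a model better by ≥ 10 BIC in every participant yields pXP > 0.99.

## Recovery designs and problem sizes

Parameter recovery simulates 40 participants × 225 trials from the GLA with
parameters drawn over the empirically reported ranges (θ ∈ [0.1, 0.95],
λ ∈ [0.05, 0.65]; β ∈ [0.4, 0.8], the range where the model's accuracy at the
true parameters brackets the ≈ 74 % correct predictions reported for this
model class), refits, and summarises true-vs-recovered correlation and
regression slope per parameter. θ and λ recover with r ≈ 0.8–0.95 and slope
near 1; β does not (it trades off against the value scale set by α and the
leak) — the same pattern motivating recovery analyses of this model class to
focus on θ and λ.
Model recovery generates data from each of {GLA, GB_dyn, GB_stat, PT, MDFT}
(8 synthetic participants per generator), fits all six models, and compares
pXP per generator: the gaze-using generators and MDFT are identified;
PT-generated data at these noise levels is parsimony-dominated by the random
model, a BIC-penalty effect, not a fitting failure.

These sizes (and the reduced differential-evolution budgets: popsize 8–10,
40–60 generations) are the package's default desk-scale study conditions;
the switchboard analysis script fits the 160 classes on a 4-participant
subset, which suffices to rank switch levels.

## Known limitations

* The gaze generator's Markov structure omits value- and comparison-driven
  gaze; analyses that depend on that structure (decoy-dwell median split,
  curve overlays for gaze-independent models) will not reproduce empirical
  signs.
* GLA agents with the empirically typical weak discount (θ ≈ 0.7) produce
  attraction RST ≈ 0.5; sizeable simulated attraction effects require a
  stronger discount (θ ≲ 0.5) — consistent with the reported finding that
  this model underestimates strong attraction effects.
* MDFT's analytic choice probabilities inherit the CLT approximation above.
* Response times are emergent from the gaze process; no model here predicts
  them.
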