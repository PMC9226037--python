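# Methods

This note documents the models, the generative assumptions behind the
synthetic cohorts, the sampler, and the numerical choices made where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task and decision variables

Each trial presents a gamble with four outcome/probability pairs. Outcomes
are drawn from N(0, 18 SEK), rounded to the nearest 5 SEK (ties away from
zero — the grid examples 13.4 → 15 and −7.9 → −10 do not disambiguate ties,
so away-from-zero was fixed as a design choice), and the whole gamble is
redrawn until all constraints hold: four distinct nonzero outcomes, each
|x| ≤ 75 SEK, and |EV| ≤ 25 SEK. The rejection loop redraws outcomes *and*
probabilities together, with an attempt cap of 10,000.

Outcome probabilities are drawn from a symmetric Dirichlet. The
concentration is the one genuinely free choice in the generator; it is
calibrated against the emergent EV distribution, which should be
approximately normal with SD ≈ 10 SEK. A flat simplex (α = 1) yields
SD ≈ 11.0 SEK; the default **α = 2.5** yields SD ≈ 10.2 SEK and mean ≈ 0 and
was fixed before the tests were frozen. The concentration is exposed in
`GambleConfig` for sensitivity analyses.

Per-trial decision variables: EV = Σxᵢpᵢ; uncertainty U = Σ(xᵢ−EV)²pᵢ,
square-root transformed and then mean-centered *within participant* (one
50-trial session) — the within-participant scope mirrors the
within-participant standardization of the ratings; prediction error
PE = outcome − EV for accepted gambles and exactly 0 for rejected ones (the
feedback screen shows "0 SEK").

## Affect-integration model

Momentary affect (valence or arousal, each fitted independently) is

AE_t = w₀ + Σ_k w_k · Σ_{j≤t} γ^(t−j) X_{k,j},  X ∈ {EV, U, PE, |PE|},

computed with the O(T) recursion S_t = γS_{t−1} + X_t, S₀ = 0 (no
pre-experiment carry-over; with standardized ratings the baseline is
absorbed by w₀). The test suite keeps the literal O(T²) double sum as the
correctness oracle. Predictors enter in natural units (SEK for EV and PE,
centered √SEK for U). Observed ratings are AE_t plus iid Gaussian noise
with an individual scale σ (the individual-variance hierarchy is lognormal).
Model variants (realized outcome instead of EV/PE, dropping U, signed-only
or magnitude-only PE) are assembled from `AffectModelSpec` flags.

## Choice model

Prospect-theory utility u(x) = x^ρ (gains) / −λ(−x)^ρ (losses), subjective
gamble value V = Σuᵢpᵢ, acceptance probability logistic(c·V) with
c ∈ [0, 20]; c = 0 is fully random choice. Trial-level modulation shifts
each parameter additively on the natural scale by the ratings reported at
the end of the previous trial (plus optional previous-outcome / previous-PE
control regressors), then clips to the admissible ranges (λ_t ≥ 0, ρ_t ≥ 0,
c_t ∈ [0, 20]); no link function is used for the trial-level regression, and
the clipping convention is a documented design choice. The first trial has
no prior rating and uses zero regressors — on the standardized scale that is
the individual's mean state. With all modulation weights at zero the
modulated likelihood equals the base model's exactly; this nesting is
asserted in the tests and underpins the WAIC comparison.

## Hierarchy, priors, links

Each individual parameter is sampled on an unconstrained scale where the
population distribution is normal: identity links for regression weights,
log links for λ, ρ and σ, a logistic (unit-interval) link for γ, and a
20-scaled logistic link for c. Hyperpriors are weakly informative:
standard normal on group means (unconstrained scale), half-normal(1) on
group scales. The γ hierarchy is therefore logit-normal rather than a beta
family — one machinery for every parameter, with the unit-interval support
preserved.

## Sampler

No general-purpose MCMC engine is part of the package's dependency set, so
inference uses a purpose-built blocked sampler that exploits the model
structure (participants are conditionally independent given the
hyperparameters):

1. component-wise adaptive random-walk Metropolis on the individual
   parameters, proposed and accepted for all participants simultaneously in
   one vectorized likelihood call;
2. conjugate Gibbs draws for the group means;
3. stepping-out slice sampling for the group scales (on log τ);
4. an interweaved non-centered step: holding z = (θ−μ)/τ fixed, (μ_k, log τ_k)
   take a joint Metropolis step through the data likelihood (the
   ancillarity–sufficiency interweaving strategy). The non-centered half is
   what keeps the hyperparameters mixing when individual-level information
   is weak.

Proposal scales adapt only during warmup (diminishing Robbins–Monro
updates, targets 0.35 / 0.234), so post-warmup draws come from a fixed
kernel. The default profile is 8 chains × 3000 iterations with 1000 warmup
(16,000 retained draws); the fast profile used throughout the tests is
4 × 1000 with 500 warmup. Chains are seeded independently and run
sequentially; fits are exactly reproducible given a seed.

Diagnostics: classic split-R̂ (fits are flagged non-converged if any
hyperparameter R̂ ≥ 1.01), narrowest-window HDIs, and WAIC
−2(lppd − p_waic) with the sample-variance (n−1) penalty. WAIC is
aggregated at the **participant** level for choice models (trial
log-likelihoods summed within participant first) and at the **trial** level
for affect models; the latter scope is a documented decision, not a stated
convention. Posterior-predictive checks simulate full cohorts from random
posterior draws, re-standardize each simulated participant, and compare the
cross-participant trial-average trajectory with the envelope and median of
the simulations.

## Synthetic cohorts

`simulate_cohort` closes the generative loop per participant: draw
individual parameters from the group distributions, generate the session's
gambles, then per trial modulate (λ, ρ, c) by the previous raw emitted
ratings, draw the choice, realize the outcome, update the affect traces,
and emit noisy ratings. The modulating input during generation is the raw
emitted rating; the analysis pipeline standardizes within participant
afterwards, so fitted modulation weights are recovered up to the (≈ unit)
realized rating SD.

Default generating values sit near the published group posteriors and are
illustrative: choice λ = 1.02, ρ = 0.55, c = 1.8 with arousal modulation
(+0.04, −0.085, +0.37) and null valence modulation; affect weights follow
the published valence/arousal pattern **interpreted per 10 SEK** for the
SEK-unit predictors (e.g. w_EV = 0.026/SEK), because per-SEK weights of
that magnitude would be inconsistent with unit-variance standardized
ratings when EV has a 10 SEK spread. The rating-noise scale σ = 0.8 makes
the generated raw ratings roughly unit-variance, so standardization is
approximately scale-preserving. Individual spreads (e.g. log-scale SD 0.3
for λ) are unreported quantities chosen once at plausible magnitudes.

The default cohort is 108 participants: one same-response contaminant
(simulated as a gain-chasing always-accepter, λ = 0, ρ = 1, c = 20) and six
static-slider contaminants (ratings stuck at the slider default position in
~95% of trials), matching the recruited-to-analysed attrition. Exclusion
rules use strict inequalities (("more than 80%")): > 80% identical choices,
or > 80% of trials with both ratings exactly at the slider default. Ratings
standardization uses the sample SD (n−1); exactly constant series map to
zeros with a degenerate-variance flag.

What the generator does **not** emulate: reaction times, payment draws,
demographics, slow drifts in engagement, any dependence of ratings on
anticipated (rather than experienced) outcomes, and probability weighting
in choice. Passing tests therefore certify the estimation machinery under
the model's own assumptions, not the behaviour of real participants.

## Parameter recovery

`run_recovery` draws random group locations (λ ∈ [0.5, 2.5], ρ ∈ [0.3, 1.3],
c ∈ [0.5, 4] on the natural scale — ranges chosen to straddle the documented
failure regime) and random group spreads, simulates a base-model cohort,
refits it, and records group and individual truth-vs-estimate pairs with
95% HDI coverage. The desk profile (10 datasets, N = 30, 50 trials, fast
sampler) is the default and the CI gate; the full-scale profile
(100 datasets, N = 101, default sampler) sits behind
`RecoveryConfig.paper_scale()` with a runtime warning. At desk scale with
group c < 2, group λ and ρ are recovered (truth inside the 95% HDI in
≥ 9/10 datasets; individual correlations ≈ 0.95), while the
high-consistency regime (c > 2 with ρ > 1) shows the expected inflation and
positive bias of the group-c estimate.

## Numerical notes

* |x|^ρ is computed as exp(ρ·log|x|) with the exponent capped at 80 so that
  absurd proposals yield a finite, hugely negative log-likelihood instead
  of NaN; the log link is similarly capped at exp(50).
* Acceptance log-probabilities use `logaddexp` throughout.
* Slice sampling for τ operates on log τ with stepping-out width 1 and is
  bounded to log τ ∈ [−9, 6].
* HDIs scan contiguous sorted windows (exact for unimodal samples) and
  require ≥ 100 draws.
* The CSV interchange format writes floats with `%.17g` and reads with
  round-trip precision, so tables survive a write/read cycle bit-exactly.

## Known limitations

* The sampler is random-walk based; for very large cohorts or weakly
  identified variants, the default profile may need more iterations than a
  gradient-based sampler would.
* WAIC values depend on the data actually fitted; only *differences*
  between models on the same data are meaningful, and desk-scale magnitudes
  are smaller than full-scale ones.
* Group "locations" are reported as link-transformed group means (medians
  on the natural scale); for the log-linked parameters this differs from
  the natural-scale mean by a factor of exp(τ²/2).
* The trial-level modulation uses post-hoc clipping rather than a smooth
  link; posterior mass near a clipping boundary indicates the additive
  parametrization is straining.
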