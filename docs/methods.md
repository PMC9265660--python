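# Methods

This note records the model, the defaults, the numerical choices, and what
the synthetic-data experiments do and do not establish.

## Model and procedure

The pipeline measures input-oriented efficiency of J units over T periods
with m inputs, one or more desirable outputs, optional undesirable outputs,
and p environmental covariates.

1. **Stage 1.** Every unit-period observation is scored by the epsilon-based
   measure (EBM) against a single *global* reference technology containing
   all J·T observations. The EBM objective `θ − ε Σ wᵢ sᵢ⁻/x_ik` spans the
   radial model (ε = 0) and a slacks-based measure (ε → 1). Four score
   batteries are produced: global/contemporaneous × CRS/VRS, each with and
   without super-efficiency. Undesirable outputs are treated as input-side
   variables by default (they should contract); a weak-disposability mode
   (equality constraints) is available for sensitivity.
2. **Stage 2.** For each input, the total contraction gap
   S = (1−θ)x + s⁻ from the *capped* (non-super) CRS run is regressed on the
   covariates under a half-normal composed-error frontier,
   S = zβ + v + u, u ≥ 0. Maximum likelihood is parameterized as
   (β, ln σ², logit γ) with σ² = σᵤ²+σᵥ², γ = σᵤ²/σ². The JLMS estimator
   E[u|ε] = μ* + σ* φ(μ*/σ*)/Φ(μ*/σ*), μ* = εσᵤ²/σ², σ*² = σᵤ²σᵥ²/σ²,
   splits each residual; f̂ + û + v̂ reconstructs S exactly.
3. **Adjustment.** X* = X + [max f̂ − f̂] + [max v̂ − v̂]: every observation is
   moved to the least favorable observed environment and worst luck, so
   X* ≥ X with equality only at the observation attaining both maxima.
4. **Stage 3.** The adjusted panel is re-scored with the same battery
   (ε and weights recomputed by default, switchable).
5. **GML.** Productivity change uses non-super-efficiency ratio scores:
   GML = E_G(t+1)/E_G(t) with GEFC/GETC/GPEC/GSEC/GPTC/GSTC defined so the
   three multiplicative identities hold by construction; the global
   reference makes the index transitive.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon_x` | affinity-index | EBM radial/slack mix in [0,1]; data-driven from the eigenvalue of the inter-input affinity matrix |
| `input_weights` | affinity eigenvector | slack weights, nonnegative, sum 1; cover bads in as-input mode |
| `super_efficiency` | on (ranking tables) | off inside GML and for Stage-2 slacks, where capped scores keep gaps nonnegative and ratios well-defined |
| `bad_output_mode` | `as-input` | `weak-disposability` imposes Σλ b = b_k instead |
| `slack_basis` | `total-gap` | `(1−θ)x + s⁻`; `pure-slack` uses s⁻ only |
| SFA multi-start | γ₀ ∈ {0.1, 0.5, 0.9} + COLS | fixed order ⇒ deterministic fits |
| LP tolerance | 1e-9 | HiGHS primal/dual feasibility; score comparisons at 1e-7 |

Stage-2 slacks come from the non-super run because super-efficiency scores
(θ > 1) would make the gap negative; super-efficiency remains a Stage-1/3
ranking device. A slack column whose standard deviation is below
1e-5 × mean(x) is treated as degenerate (everyone on the frontier): no
regression is fitted and the input is left unadjusted.

One regression per input is fitted on the pooled J·T observations; the max
operators of the adjustment range over the same pool. γ = 0 is handled as an
explicit boundary candidate (the likelihood then equals OLS exactly), so the
reported likelihood never falls below the OLS likelihood and a flat γ̂ is
flagged (`gamma_boundary`). The one-sided test of γ = 0 uses the equal-weight
chi-square mixture (critical value 2.706 at 5% for one restriction), not the
naive chi-square.

## The synthetic world

`generate_panel` draws a constant-returns frontier x*ᵢ = aᵢ·y / trendᵗ with a
2 %/yr technology trend, then inflates each input additively:
X = x* + f + u + v with f = (zβ)·x̄ᵢ, u half-normal (σᵤ = 0.55 of the input's
typical level, Gaussian-copula persistence 0.9 over time and 0.85 across
inputs — management quality is a stable unit trait that wastes all inputs
together), and v Gaussian (σᵥ = 0.02). Emissions are a joint product of
output whose intensity falls with the trend. Ground truth (frontier inputs,
components, true β, management-only efficiency) is returned alongside the
panel, and X always reconstructs exactly from the stored components (the
rare floor clips, < 1 % of cells by calibration, are absorbed into v).

Three design choices are *stated assumptions*, found by experiment to be
necessary for the adjustment to be identifiable at J = 13 — the method does
not merely prefer them, it fails without them:

- **Near-homogeneous unit scales** (`weight_profile = 0.03`). The additive
  leveling in the adjustment is not translation-invariant under constant
  returns: with unit sizes spread by a factor of 2–3, adjusted scores end up
  tracking unit size (correlation ≈ 0.98 in our experiments) instead of
  management. DEA's own homogeneity requirement is made explicit here.
- **Predominantly transient environment** (`env_unit_sd = 0.15`,
  `env_noise_sd = 1.3`, one shared factor across covariates). With p = 5
  covariates and J = 13 units, a *persistent* environment is statistically
  inseparable from persistent management — the slack regression's chance
  projection absorbs roughly p/J ≈ 40 % of persistent management variance.
  Year-to-year covariate variation identifies β from all J·T observations.
- **A shared sign pattern of β across inputs** (magnitudes differ). The
  radial part of a DEA input gap is common to all inputs, so covariate
  effects whose sign flips between inputs cannot be disentangled from slack
  regressions.

Calibration (done once): stage-1 score spread across units ≈ 0.2–0.4,
matching the dispersion of published provincial efficiency tables; γ̂ close
to 1 in the slack regressions (management dominates noise — also the
empirical finding this class of studies reports, and a *precondition* for
the adjustment: when γ̂ is materially below 1, the estimated luck term v̂
inherits part of u and the luck-leveling then partially cancels true
management differences).

What a green recovery test establishes: on panels from this generator, the
pipeline recovers all slack-coefficient signs and stage-3 scores track true
management efficiency more closely than stage-1 scores (mean within-year
rank correlation, margins ≈ +0.3–0.4). What it does not establish: recovery
under heterogeneous unit sizes, persistent confounders, sign-flipping
covariate effects, or real yearbook magnitudes — the generator does not
emulate tonnes and hectares, spatial correlation between neighbors, or
actual carbon coefficients.

Correlations with truth are evaluated *within years* and averaged: global
frontier scores embed the technology trend (early years are mechanically
further from the frontier) while true management efficiency is trend-free,
so pooled correlations would be contaminated in both stages.

## Numerical and degenerate-input choices

- LPs are solved in primal envelopment form by HiGHS; VRS super-efficiency
  infeasibility falls back to the non-super score with a counted
  `fallback-used` status.
- Alternate-optimum slacks are taken from the solver's basis; scores are
  unique, slack non-uniqueness is a known DEA property.
- Φ in the JLMS formula is evaluated in the log domain, so extreme negative
  ratios never divide by zero.
- The affinity index of two input profiles is 1 − 2·mean|c−c̄|/(max c − min c)
  with c the log ratio; exactly proportional columns (range < 1e-12) get
  affinity 1, m = 1 degenerates to (ε = 0, w = [1]).
- Ties in ranking tables break by unit label and are flagged.
- Weighted "period average" cells compute weighted means per year and then
  average years; a pooled-weights alternative is switchable.
- Growth rates are CAGR over T−1 intervals. Report tables round to 3
  decimals (efficiencies, indices) and 2 (percentages).

## Known limitations

- Only input orientation; no output-oriented or non-oriented EBM, no
  network/dynamic DEA, no bootstrap inference.
- Half-normal inefficiency only (no truncated-normal or exponential), no
  heteroskedastic σᵤ(z), no time-varying inefficiency.
- The desirable-output slack term is not rewarded in the EBM objective, so
  the program stays linear without the Charnes–Cooper transform.
- The Stage-2 regression inherits every measurement artifact of DEA gaps
  (frontier estimation noise, radial mixing across inputs); γ̂ is therefore
  biased downward relative to the generating γ, and the luck-leveling term
  removes a corresponding fraction of true management differences.
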