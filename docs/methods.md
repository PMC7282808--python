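# Methods

## Generative model and inference

An observation is a D-dimensional feature vector summarizing one recording
session.  The animal's assumed generative process first samples a hidden
state from a Chinese restaurant process (CRP) and then samples the
observation from that state's distribution, with the state's parameters
drawn once from a conjugate prior and never observed.  Inference inverts
this: given a set of observations and a candidate assignment of
observations to states (a partition), the unnormalized log posterior is
the sum of per-state marginal likelihoods plus the CRP log prior

    log P(c) = K log α + Σₖ log Γ(mₖ) + log Γ(α) − log Γ(T + α),

which equals the product of the sequential CRP terms and is a normalized
distribution over partitions (the test suite verifies both by exhaustive
enumeration for T ≤ 6).  All probability arithmetic is in log space via
log-gamma; α = 0 is accepted as the degenerate single-state prior, and a
multi-state partition under α = 0 scores −∞ rather than raising, so
evidence ratios stay well defined.

Reported quantities are log odds between named hypotheses.  Sign
conventions are explicit in every result (`numerator`, `denominator`
fields; quantity names such as `log_odds_one_state_vs_two_states`), and
any axis flipping is left to the consumer — never done inside the math.
Hypothesis-set comparisons (the morph protocol's S-vs-D construct) score
each hypothesis as training-partition posterior plus the probe's
assignment term and combine sets with log-sum-exp, using exactly the five
named hypotheses rather than all partitions.

## Gaussian family (linear features)

Normal-Wishart prior with μ₀ = 0, κ₀ = 10⁻³, ν₀ = 0.02, T₀ = 0.02·I.
The posterior predictive after m observations is a generalized Student-t
with df ν_m − d + 1, location μ_m and scale T_m(κ_m + 1)/(κ_m(ν_m − d + 1));
the scatter term in T_m is the centered scatter matrix (zero for m = 1).
Marginal likelihoods are computed as the exact chain of one-step
predictives; the chain is validated against brute-force 2-D quadrature of
the normal-gamma mixture (1e−3 relative).

**Degrees-of-freedom floor.** With ν₀ = 0.02 the empty-state predictive is
improper for d > 1 (df = ν₀ − d + 1 ≤ 0).  All computations therefore use
ν₀_eff = ν₀ + d − 1, the minimal proper correction; it coincides with the
nominal prior for d = 1.  A consequence worth knowing: the novel-state
predictive has df ≈ 0.02 in every dimension count — so heavy-tailed that
it is nearly flat over several units.  This caps how negative a
same-vs-novel evidence ratio can get (≈ −13 nats for the 4-feature
protocol) and makes moderate-distance probes land near the uncertainty
region rather than at extreme negative values.

## Von Mises family (circular features)

Von Mises likelihood with a normal-gamma prior: μ | κ ~ wrapped
Normal(μ₀, 1/(κ₀κ)) and κ ~ Gamma(a₀ = 0.01, b₀ = 0.01) (shape/rate).
The coupling of μ's precision to κ is the standard normal-gamma
construction; multivariate circular observations factor as independent
per-dimension models.  No closed form exists, so marginals and
predictives are trapezoid quadratures on a grid of 720 uniform μ points ×
64 log-spaced κ points over κ ∈ [10⁻³, 10³] (resolutions configurable; a
test doubles both and requires < 10⁻³ change).  Angles are degrees at the
API and radians internally; circular densities are reported per degree.

**Truncated, renormalized prior.**  Gamma(0.01, 0.01) places ~90% of its
mass below κ = 10⁻³, where the Von Mises is indistinguishable from
uniform.  The (μ, κ) prior is renormalized on the grid support, which
makes marginals telescope exactly into chains of predictives and keeps
any truncation constant out of evidence ratios.  The practical effect of
dropping the sub-grid mass is a slightly thinner "uniform cushion" under
very diffuse data; comparisons between partitions of the same
observations are unaffected to first order.

## Reference-direction (offset) inference

Circular cue vectors are compared up to a global rotation: for each
trained state, the offset φ maximizing the joint posterior predictive of
(y − φ) is found on a uniform 1° grid (matching the integer-degree
reporting convention), one global φ across all circular dimensions.
Offsets are reported in (−180°, 180°]; ties break toward the smaller grid
offset.  A novel (empty) state uses φ = 0 — immaterial because the prior
predictive is flat to ~0.5%, which also bounds the residual dependence of
offset-corrected evidence on absolute orientation.  The offset grid is
searched efficiently by exploiting that both the offset and μ grids are
uniform on the circle, reducing the profile to gathers against a
720-point Von Mises kernel per κ node; the fast path is checked against
the direct quadrature to 1e−9.

## Population profile

An evidence ratio maps to a Beta(a, b) distribution of per-cell
rate-modulation extents: the preferred hypothesis's parameter is
|ratio| + 1, the other 1 (hence ratio = b − a).  Thresholds 0.15/0.85
split the population into no-remap / rate-remap / complete-remap
fractions via the regularized incomplete beta function (no sampling).
Closed-form fractions are used as ground truth; e.g. Beta(1, 7) gives
32.1%/67.9% rate/no-remap where rounded 31%/69% figures also circulate —
the ~1-point difference is a rounding/sampling artifact of the latter.

## Protocols: study conditions and defaults

One observation = one session.  All protocol defaults are the stated
study conditions; α = 0.1 except where a protocol sweeps α.

* `cue_constellation` — 4 Gaussian features (mean 0, sd 0.2), 20 training
  sessions, probes with 0/1/2/4 cues set to 1.
* `alternation_learning` — alternating 1-D Gaussians, means (−1, +1)
  (or (0, 0) for the stabilization variant), sd 0.3; the evidence ratio
  is evaluated after each pair; 20 pairs by default (enough for both
  variants to saturate their sign); supports an α list for the
  variability sweep.
* `direction_foraging` — 10 circular observations, uniform vs alternating
  Von Mises (means 0°/180°, κ = 10); the two-state split is the
  maximum-margin diameter (1° grid, smallest-angle tie-break).
* `cue_rotation` — 10 training sessions; cue card wrapped normal
  (mean 0°, sd 18°); dirty variants add 5 cues with uniform random means
  (drawn once per run, reused in the probe) and sd 54°; offsets on a 1°
  grid.
* `morph_test` — training as in `alternation_learning`; probes on a grid
  between the extremes, evaluated after 5 and 25 sessions; S/D hypothesis
  sets as named in the inference module.
* `schedule_hypotheses` — 2-D sessions (shape, color features); white
  circle [1, 1], morph circle [1, −1], morph square [−1, −1], all sd 0.1.
  The original training schedule is not numerically specified anywhere we
  could rely on, so the default is three alternating white-circle /
  morph-circle pairs followed by three morph-square sessions, fully
  configurable.  The default α list spans 10⁻¹² to 10: with sd 0.1 and
  unit-scale separations the likelihood differences are O(10²) nats, so
  preference shifts between the three named partitions only appear when
  α varies over many decades.
* `cue_variability` — 20 training sessions from N([−5, 0], diag[2, 0.1]²)
  (cyan) or N([0, 0], diag[0.1, 2]²) (magenta); the probe is not uniquely
  determined by the source description, so the default [−1, 0] is chosen
  to be ≈2 sd from the cyan mean but ≈10 sd from the magenta mean in
  feature 1, realizing the intended contrast; configurable.

Every protocol is a deterministic function of (config, seed); replicate
analyses derive child seeds from a single SeedSequence so adding a probe
never perturbs training draws.

## What the generators do and do not emulate

Sessions are exchangeable i.i.d. draws given the schedule; there is no
within-session sampling process, no sensory noise model beyond the stated
distributions, no temporal autocorrelation, and no spatial firing-rate
geometry.  Passing tests therefore show that the *inference* behaves as
claimed under the stated observation statistics — not that real neural
data have those statistics.

## Known behaviors and limitations

* **Dirty 180° rotation is bimodal across seeds.**  The cue card's
  misfit at offset 0 (≈ −9.9 nats) and the five extra cues' joint misfit
  at offset 180 (≈ −9.9 nats) are statistically tied, so ~60–65% of seeds
  keep the map (offset near 0°) and the rest follow the card.  The
  circular mean over seeds still sits near 0° because the ±180° cluster
  self-cancels.  The same-state evidence stays positive in ~94% of seeds
  and is always much closer to 0 than the clean case.
* **The directional-foraging two-state preference is marginal.**  At the
  stated conditions the split's likelihood gain (8.5 ± 1.9 nats) almost
  exactly offsets the CRP penalty (8.75 nats): the two-state hypothesis
  wins outright in ~40% of seeds, while the *comparative* statement —
  directional observations favor two states more than uniform ones — holds
  in ~98%.  This is the partial-remapping boundary, not a numerical
  artifact.
* **The all-cues-changed probe is weakly negative.**  Because of the
  heavy-tailed novel-state predictive (df floor above), the 4-cue probe's
  same-vs-novel ratio averages −2.3 ± 3.7, negative in ~75% of seeds;
  the monotone ordering across probes (0 > 1 > 2 > 4 cues changed) is
  robust.
* Exhaustive partition enumeration is guarded to T ≤ 10; protocol code
  compares small named hypothesis sets only.
* The CRP expected state count α·log N used as a sanity anchor is the
  asymptotic leading term; the exact finite-N expectation
  α(ψ(α + N) − ψ(α)) is what simulations are tested against.

## Problem sizes

Test-suite and acceptance computations use the stated per-protocol sizes
(10–50 sessions), 50–100 replicate seeds for distributional claims, 2000
replicates for the CRP state-count check, and the 720 × 64 quadrature
grid; these match the study conditions while keeping the whole suite
comfortably within a coffee break on one CPU.
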