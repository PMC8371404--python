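# Methods

## The forward model

A wh-question over a domain of k named individuals ("Which of Audrey, Bob,
Dale danced?") partitions the possibilities into 2^k partial states, one per
subset B of the domain (the *target set*: exactly the members of B acted).
States are encoded as bitmasks with the alphabetically first name at the
least-significant bit; the package canonicalizes the individual named in the
focus answer to bit 0, so the *exhaustive* state — only the mentioned
individual acted — is always state index 1.

Interpretation follows the standard three-level rational-communication
recursion. A literal listener conditions a prior over states on the literal
meaning of the utterance,

    L0(s | e) ∝ [[e]](s) · p(s),

a speaker chooses among true utterances by a soft-max over utilities

    S1(e | s) ∝ exp(α · (log L0(s | e) − C(e))),

and a pragmatic listener inverts the speaker by Bayes' rule,

    L2(s | e) ∝ S1(e | s) · p(s).

α ≥ 0 is the speaker's decision-noise (soft-max temperature): α = 0 picks
uniformly among true utterances, large α approaches the strictly optimal
speaker. α = ∞ is not represented; `RSAParams` warns above α = 100, where
the optimal-speaker limit is reached for all practical purposes.

**Lexicon.** The default lexicon contains one prosodic-focus expression per
nonempty subset, with *at-least* semantics ([[FOC_B]](s) ⇔ B ⊆ B_s), plus a
zero-cost null message true in every state. The null message matters: it is
what a cooperative speaker falls back on in the empty state, and the closed
form below is reproduced by the full matrix recursion only under this
convention (verified analytically at α ∈ {0, 3}, k = 2, p = 0.5 and
numerically on a k × p × α grid to 1e-10). Without it, states with no true
expression get an all-zero, flagged speaker row rather than an error, so the
null-free configuration remains usable.

**Prior.** Each individual is assumed to act independently with probability
p, giving the "binomial" state prior p(s) = p^m (1−p)^(k−m) for a target set
of size m.

**Exhaustivity.** E(k) = L2(s_exh | FOC naming one individual). Under the
default convention it obeys the closed form

    E(k) = E(2)^(k−1),   E(2) = 1 / (1 + (1 + p^−α)^−1 · p/(1−p)),

which the test suite holds against the full recursion to 1e-10. E(k) is
strictly decreasing in k and in p: the central qualitative prediction that
the experiments probe.

**Variants.** All variants preserve the drop in E(k):

* *Costs*: C(e) = cost_per_word × (number of focused names), exclusives one
  word extra. Costs steepen the drop.
* *Exclusives*: adding "only B"-type alternatives (true exactly at B)
  lowers E(k) at every k.
* *Collapsed two-state space*: listener entertains only {s_exh, s_nonexh}
  with two alternatives ("A acted" / "A and at least one other acted");
  the non-exhaustive binomial mass is pooled, so s_nonexh keeps prior
  1 − (1−p)^(k−1) and the drop steepens rather than disappearing.
* *Constant-prior collapsed space*: both states fixed at probability 0.5
  for every k — the only variant with flat E(k), at the price of giving up
  probability calculus over the state space.
* *Uniform back-off*: `backoff_prior` mixes the prior with the uniform
  distribution (weight 1 = pure back-off); since the uniform prior over a
  growing state space still dilutes the exhaustive state, it does not
  flatten E(k) either.

## The hierarchical slider models

Beliefs are elicited as slider ratings in [0, 1], one slider per state
(prior probes show all 2^k states; posterior probes the 2^(k−1) states
compatible with the utterance). Because states of equal target-set size are
conceptually interchangeable, participant j's beliefs at domain size k are
parameterized by a simplex p_jk over sizes 0..k only, expanded to states by
Q_i = p_{j,m_i} / C(k, m_i).

Prior-probe model:

    κ  ~ Gamma(5, 5)          w  ~ Gamma(2, 0.1)
    σ² ~ inv-Gamma(1, 1)      μ_k ~ Dirichlet(1, …, 1)
    p_jk ~ Dirichlet(w · μ_k)
    logit(P_ijk) ~ Normal(κ · logit(Q_ijk), σ)

All Gamma distributions use the shape–rate convention. κ scales the logit
and captures endpoint aversion (κ < 1) or affinity (κ > 1); κ = 1 means
sliders map linearly to beliefs on the logit scale. The κ·logit(·) link is
one of several forms consistent with "a logit transformation controlling
endpoint aversion"; it is adopted because κ ≈ 1 then reads directly as
"sliders ≈ beliefs".

Posterior-probe model: participant beliefs are conditioned on the utterance
and pushed through the speaker,

    Q_post(i) ∝ S1(foc | i; α_j) · Q_prior(i),
    α_j ~ Gamma(μ_α²/σ²_α, μ_α/σ²_α),   μ_α ~ Gamma(5, 5),
    σ²_α ~ inv-Gamma(1, 1),

with (w, μ_k) fixed at the posterior means of the prior-probe fit and
(κ, σ²) refit. One α_j per participant, shared across that participant's
items, absorbs between-item spillover: consistently extreme exhaustive
sliders are explained by a larger or smaller α_j.

**The bridge's alternative set.** The speaker term in `rsa_bridge` is
computed on the compatible subspace: states are the 2^(k−1) bitmask states
containing the mentioned individual, the prior is the participant's
conditioned belief vector, and the lexicon is the focus lexicon (plus null)
with denotations restricted to that subspace. At k = 2 this choice provably
reproduces both the full-space model and the closed form (the speaker ratio
equals (1 + p^−α)^−1). Normalizing the speaker on the full state space
instead requires beliefs about incompatible states that the conditioned
model no longer represents; the subspace convention keeps the bridge a
function of exactly the quantities the hierarchy carries.

**Response-scale saturation.** Slider values are clipped to
[1e-4, 1 − 1e-4] before the logit, and the channel mean applies the same
clip to the state probability. The two clips must match: sliders cannot
express distinctions finer than their resolution, so a predicted state
probability of 1e-6 and an observed response of 1e-4 should agree, not
register as a many-sigma residual. (An asymmetric clip measurably biases
the rationality estimates downward — sharp speakers are exactly the ones
that produce out-of-resolution predictions.)

## Sampling

No general-purpose gradient-based PPL is a dependency; the samplers are
adaptive Metropolis-within-Gibbs, written for this model family:

* positive scalars move by Gaussian random walks on the log scale,
  simplices on additive-log-ratio coordinates (with the exact Jacobians);
* per-participant blocks (p_jk, α_j) are conditionally independent given
  the population level and are proposed and accepted jointly in one
  vectorized step per domain size, with per-participant proposal scales;
* all chains are advanced in lock-step as one array axis;
* population-level blocks that touch only O(J) density terms (w, μ_k,
  μ_α, σ²_α, and κ/σ² through cached bridged beliefs) are swept several
  times per iteration — mixing insurance at negligible cost;
* the posterior model additionally uses a joint "ridge" move that rescales
  every α_j and counter-rotates κ, the direction along which sharper
  speakers trade off against a steeper response link;
* proposal scales adapt by Robbins–Monro toward ~0.3 acceptance during the
  warmup half and freeze afterwards (preserving detailed balance for every
  retained draw);
* initialization is from moment estimates (observed size-class shares for
  p_jk; an inversion of the two-state bridge on each participant's observed
  exhaustive share for α_j), jittered per chain.

Defaults follow the reference analysis where stated: 4 chains, 50% warmup,
thinning factor 5; 2,000 iterations per chain is the desk-scale default and
`McmcConfig.paper_scale()` selects 50,000. Split R-hat (via arviz) is
reported for every population-level parameter; a fit with any R-hat ≥ 1.05
is flagged (`converged=False`, with a warning), never silently returned.
Identical seeds yield bitwise-identical draws.

Posterior-predictive machinery: population-average HDIs simulate a fresh
cohort per retained hyperparameter draw, push it through the response
channel, renormalize per item and take highest-density (not equal-tailed)
intervals; per-item posterior predictive p-values use each participant's own
draws, with the observed normalized exhaustive-state response as test
statistic and two-sidedness by doubling the smaller tail (capped at 1).

## The synthetic experiments

The generator emulates the two designs' statistical structure:

* Experiment 1 — one slider per state; three items per participant pairing
  the three scenarios with k ∈ {2, 3, 4}; 30 prior-probe and 66
  posterior-probe participants (retained, i.e. post-exclusion).
* Experiment 2 — two sliders everywhere (exhaustive vs pooled
  non-exhaustive); prior probes are elicited knowing one individual acted,
  so both probes share the conditioned state space; extra "none"/"all"
  arms at fixed k = 2 with one item each (arm sizes 49/82, 65/60, 28/63).

Prior-type presets are binomial size distributions with success probability
0.27 / 0.47 / 0.70 for "none" / "some" / "all", chosen so the population
exhaustive-state prior on the conditioned k = 2 space is exactly
0.73 / 0.53 / 0.30 — the ~20-percentage-point swing around the mid prior
that the wording manipulation is reported to produce. The "some" preset is
the default generator prior everywhere. The default population rationality
is μ_α = 2.0: with the k = 2 bridge it places model posteriors at ≈ 0.97 /
0.86 / 0.57 for the three priors, matching the magnitude of the published
model-based estimates (~95 / 85 / 61%). Other defaults: κ = 1, w = 20,
σ² = 0.25, σ²_α = 1.

Response behaviors:

* `model_normalized` — responses follow the hierarchical model exactly
  (raw sums hover near 1);
* `non_normalizing` — each Experiment-1 slider responds to the
  participant's *size-class* probability p_{j,m}, not divided among the
  C(k, m) interchangeable states. Raw sums then scale like
  Σ_m C(k,m) p_m and grow strongly with k, emulating participants who do
  not renormalize across a growing slider set. The mechanism is one of
  several admissible emulations; nothing downstream depends on which one
  produced the inflation.
* `constant_null` — the raw exhaustive slider sits at a constant level
  (default 0.9) with truncated Gaussian noise at every domain size and
  prior type, other sliders independently at a lower constant (default
  0.25). This is the behavioral null: normalized exhaustivity then drops
  with k purely because the slider count grows.

Response times are log-normal (median 40 s) solely so the 15-second
exclusion rule is exercisable; configurable fractions of too-fast and
all-zero participants are appended *on top of* the designed arm size, so
the designed count is exactly what survives `apply_exclusions`. Domain
names are drawn from a bundled list of frequent first names and
alphabetized.

What passing tests on these data do **not** show: the generator contains no
scenario effects, no item-wording effects, no slider-order effects, and its
non-normalizing mechanism is an assumption; agreement between pipeline and
generator is evidence about the pipeline, not about human behavior.

## Analysis pipeline

Exclusions (any item under 15 s, or any all-zero item) → per-item
normalization (raw / item sum; idempotent) → per-condition exhaustivity
summaries (normalized and raw exhaustive-state means, raw slider sums) →
one-way ANOVA on per-participant mean exhaustive-state values (the
aggregation unit is a package choice; the reference analysis does not state
its own), at a fixed 0.05 level with no multiplicity correction → the k = 2
Bayes-consistency check.

The k = 2 check inverts the two-state Bayes identity
p(exh | foc) = 1 / (1 + s(q) (1−q)/q) for the implied speaker probability s
at each prior-type arm, and issues "consistent" only if posteriors increase
strictly with the prior, by at least `min_spread` (default 0.05 absolute —
smaller swings are below what the arm sizes can resolve), with implied s
values inside [0, 1] and non-increasing in the prior (values outside [0, 1]
are flagged, not clamped). Flat posterior profiles across substantially
different priors therefore return "inconsistent"; identical priors return
"inconclusive".

## Calibration study

`focusrsa.calibration.recovery_study` is the package's simulation-based
calibration: per seed it simulates both Experiment-1 arms at full size from
known hyperparameters (κ = 1, w = 20, σ² = 0.25, μ_k binomial with p = 0.4,
μ_α = 3, σ²_α = 1), runs the two-stage fit (prior fit, then posterior fit
with plugged-in means), and scores whether each generating value lies in its
95% HDI. Coverage is pooled over seeds and hyperparameter components;
per-seed joint coverage of ~15 quantities would be ≈ 0.95^15 ≈ 0.46 even for
a perfect sampler and is not a meaningful criterion. Note the two-stage
plug-in (the reference procedure) slightly understates uncertainty in the
posterior-stage parameters relative to a joint fit; pooled coverage a few
points below nominal is expected, not a defect.

## Numerical choices

* Row-stochastic tables validate row sums to 1e-12; rows with empty support
  are exact zeros and flagged, never NaN.
* −∞ utilities are represented by exact zero speaker probability; soft-max
  normalization subtracts the per-state maximum before exponentiating.
* α = 0 with true-but-useless expressions: 0 · (−∞) is resolved by masking
  false expressions before multiplication.
* Point-mass priors propagate through the bridge exactly (states with zero
  prior never contribute to speaker normalization).
* Ties/degenerate inputs: degenerate k = 2 priors return the forced Bayes
  limits (q = 0 → 0, q = 1 → 1).

## Known limitations

* The recursion is fixed at depth L2; no lexical uncertainty, QUD
  inference, or deeper iteration.
* The sampler is specialized to these two models; it is not a
  general-purpose PPL, and very large α (> ~100) or extremely concentrated
  beliefs will slow mixing.
* Experiment 2's pooled non-exhaustive slider is never mapped back onto
  individual non-exhaustive states — there is no unique such mapping — so
  model fitting is only defined for the one-slider-per-state design.
* The generator's defaults describe one plausible population; conclusions
  about human data require the real measurements, which the package only
  emulates.
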