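# Methods

`emolba` implements a complete analysis pipeline for two-alternative
emotion-report experiments in which participants view normed affective
pictures under a cue announcing an easy (feature) or difficult
(conjunction) upcoming visual search, and report whether the picture feels
pleasant or unpleasant. The scientific question the pipeline serves is
whether *anticipated effort* changes the rate at which emotional evidence
accumulates, over and above changing response caution.

## The decision model

Each emotion report is modelled as a race between two linear ballistic
accumulators (LBA), one per response. On a trial, accumulator *i* starts at
`start_i ~ Uniform(0, A)`, accumulates evidence at a constant within-trial
rate `drift_i ~ Normal(mean_v_i, sv)` drawn fresh each trial, and triggers
its response on reaching the boundary `b = A + B`. Observed RT is the
winning finishing time plus a non-decision time `t0`. The likelihood of a
(choice, RT) pair is the *defective density*: the winner's finishing-time
density times the probability the loser is still running. Closed forms for
the finishing-time CDF/PDF are standard; the implementation evaluates them
with explicit small-`A` and small-`t` limit branches (`A < 1e-6` switches
to the fixed-start-point form `Phi((tv − b)/(t sv))`) and floors per-trial
log densities at −700 before summation.

Accumulators are coded *normative* / *aberrant* relative to the picture's
valence norm on the 1–9 scale: a norm below 5 makes "unpleasant" the
normative report. A norm of exactly 5 is undefined and rejected; the
stimulus ranges ([2, 4] and [5.5, 6.5]) keep it unreachable in practice.

**Negative drifts.** The source analyses do not state how negative sampled
drifts are treated. The default convention here truncates each
accumulator's drift distribution to positive values (densities
renormalised by `Phi(mean_v / sv)`), which guarantees every trial
terminates — appropriate for a task in which a response always occurred
within the 8-s display. The alternative "defective" convention (negative
drifts never finish; non-terminating races are censored) is available via
`drift_convention` everywhere, and both satisfy the normalization identity
(choice probabilities plus non-termination mass sum to 1).

**Scaling.** `sv` is fixed at 1.0 for both accumulators as the scaling
constraint; it is not estimated.

## Models and priors

Two hierarchical models are defined over the 2 (pleasantness) × 2
(difficulty) cells:

* **null** — 5 subject-level parameters (`A`, `B`, `t0`,
  `mean_v.normative`, `mean_v.aberrant`), all shared across cells;
* **core** — 14 subject-level parameters: `A` and `t0` shared, `B` and the
  two drift means split by cell. The core model nests the null model
  exactly.

Subject-level parameters follow truncated-Normal population distributions
on the natural scale (lower bound 0 for `A`, `B`, `t0`; unbounded for
drift means). Population locations carry Normal priors truncated to the
support with means/SDs `A:(2, 0.6)`, `B:(2, 0.6)`, `t0:(0.3, 0.1)`,
`mean_v.normative:(2, 0.8)`, `mean_v.aberrant:(0.5, 0.8)`; population
scales carry half-Normal(0, 1) hyperpriors. The scale hyperprior and the
natural-scale (rather than log-scale) subject distribution are this
package's choices where the source toolchain's internals are not
documented; they keep the prior table's units directly interpretable.

## Estimation

Posteriors are sampled by differential-evolution MCMC: an ensemble of
chains (default 42; the scaled-down "desk" profile uses 24), each carrying
the full state (all subjects' parameters plus the population location and
scale). Per iteration:

1. **Subject blocks** — several Metropolis sweeps per subject with DE
   proposals `gamma (theta_r1 − theta_r2) + jitter`,
   `gamma = 2.38/sqrt(2d)` scaled by a Uniform(0.5, 1) draw; alternate
   sweeps update a random subset of coordinates with a correspondingly
   larger step (crossover), which beats the d-dimensional random-walk
   scaling on weakly coupled coordinates.
2. **Start-point ridge moves** — the likelihood pins the boundary
   `b = A + B` tightly while `A` is only weakly identified, creating a
   strong `A`-vs-`B` ridge shared across cells. A symmetric one-dimensional
   move shifts `A` and counter-shifts every `B` (keeping all `b` fixed),
   per subject and — as a collective variant — for all subjects plus the
   population locations at once.
3. **Population blocks** — conditional on the subjects, the (location,
   scale) pairs factorize across parameters, so each dimension is its own
   2-parameter Metropolis block with DE proposals; several cheap sweeps
   per iteration.
4. **Full-state DE move** — one proposal shifting a chain's entire state
   along a between-chain difference, which crosses hierarchical ridges that
   blockwise moves cross only diffusively.
5. **Migration** (burn-in only, probability 0.20 per iteration) — a random
   cyclic subset of chains may adopt one another's subject states and
   population states, judged by each destination chain's own target;
   protects against stuck outlier chains.

Chains start in a small cloud around each subject's penalized-likelihood
mode (a crude Nelder-Mead optimum of likelihood × prior); prior-draw
initialization is available via `init="prior"` and is used in the
prior-recovery correctness test. Draws after burn-in are thinned before
storage. Everything is driven by one seeded generator: fits are bitwise
reproducible.

Default profiles: **paper** — 42 chains, 1000 burn-in, 8000 sampling
iterations, thin 12; **desk** — 24 chains, 500 burn-in, 1500 sampling
iterations, thin 3. The desk profile is the package's development-scale
choice for simulation studies and is what the recovery analyses and the
reproduction script use.

## Convergence and model comparison

Convergence is gated on the classic two-part Gelman-Rubin potential scale
reduction factor, computed per parameter at both levels, with the
acceptability bound 1.10; the split-half variant is available behind a
flag. Degenerate (zero-variance) chains yield NaN with a warning rather
than a spurious value.

Model comparison uses the deviance information criterion per participant —
`DIC = Dbar + pD`, `pD = Dbar − D(posterior-mean parameters)`, deviance
computed from the participant's subject-level draws only — summed over
participants. Lower wins; a 6-point gap is reported as the conventional
"real difference" bar. pD can go negative under multimodality; it is
reported, not hidden.

## Inference on fitted parameters

The second stage follows the two-stage workflow: per-subject posterior
means of a fitted parameter (e.g. `mean_v.normative`) are tabulated as
participants × cells and analysed with default-prior Bayes factors.

* **2×2 repeated-measures BANOVA** over the model set {subject-only; +P;
  +D; +P+D; full}. Effects use projected orthonormal sum-to-zero
  contrasts; each term has one `g ~ InvGamma(1/2, r²/2)` (fixed-effect
  scale r = 0.5, random subject scale r = 1.0). Marginal likelihoods are
  Monte-Carlo averages over `g` (default 10^5 draws, seeded, with reported
  numerical error), evaluated through a k-dimensional Woodbury identity;
  the test suite checks them against a direct determinant-based coarse-grid
  integration. Main-effect BFs compare each one-factor model with the
  subject-only base; the interaction BF compares full against
  main-effects-only.
* **JZS paired t-tests** (Cauchy prior scale √2/2) by one-dimensional
  adaptive quadrature, used for the follow-up contrasts within each
  difficulty level and for the manipulation-check RT comparisons.
* **Percent change** on the ratio-scale drift estimates,
  `100·(m_high − m_low)/m_low`, reported to 2 decimals — e.g.
  `percent_change(3.172, 2.942) = 7.82`.

BANOVA consumes posterior means, not full posterior draws; with per-subject
point summaries the analysis matches the separate-package workflow it
emulates, at the cost of ignoring first-stage posterior uncertainty.

## Synthetic experiments

`emolba.simulate.gen_dataset` emulates the design: default 64 participants,
4 blocks × 60 trials; each block balanced 30/30 in valence and 20/20/20 in
cue, with cue × valence balanced 10 each (the counterbalancing
constraints); one normed picture per trial, each picture seen once per
participant, norms Uniform[2, 4] (negative) and Uniform[5.5, 6.5]
(positive). Subject parameters are truncated-Normal draws around
configurable population locations; trials come from the race simulator
with 8-s censoring.

Default generating values: normative drifts 2.942 / 3.172 / 2.239 / 2.148
(unpleasant-easy / unpleasant-difficult / pleasant-easy /
pleasant-difficult) and aberrant drifts 0.017 (unpleasant) / 0.742
(pleasant) — the reported cell estimates — with `A = 2`, `B = 2`,
`t0 = 0.3` (the prior central values; the source never prints its
estimated values for these) and population scale 0.2 for every parameter.
The scale and the A/B/t0 values are conventions of this package, not
reported facts. `model="null"` generates null-structured data (one `B` and
one drift pair per subject, shared across cells), which is what the
model-selection simulations require — drawing split parameters with equal
*locations* still leaves genuine per-subject cell differences.

Manipulation-check columns are lognormal search RTs with condition means
1131 / 1449 / 1832 ms (SD = 0.35 × mean; the shape and spread are
conventions) and error indicators at rates 0.137 / 0.135 / 0.139.

What the generator does **not** emulate: block-position and fatigue
effects, stimulus-category structure (faces/objects/landscapes/people),
arousal, RT contaminant processes other than the injected ones, and any
dependence of the search task on the emotional picture. Passing recovery
tests therefore show that the estimation machinery is sound under the
model's own assumptions — not that the model is right for real data.

**Preprocessing fixture.** The exclusion-pipeline round-trip tests use a
dedicated bounded-RT fixture (`make_preprocess_fixture`: uniform RTs on
[0.8, 2.0] s, all-normative responses) plus `inject_contaminants`, which
adds >50%-aberrant participants, <50%-normative pictures, out-of-window
RTs, and per-cell z outliers with exact bookkeeping. On the bounded
fixture zero spurious exclusions are structural (a uniform sample cannot
reach |z| = 3.5), so injected counts equal report counts exactly. On
LBA-generated data the RT filters genuinely remove a small fraction
(~1–2% at the default drifts) — the RT tail has real mass beyond 6.1 s —
so exact-zero round trips are not asserted there.

## Preprocessing

The four exclusion steps run strictly in order: (1) participants with
aberrant-response proportion strictly above 50%; (2) pictures whose
normative-response rate falls strictly below 50%; (3) trials with RT
≥ 6.1 s or ≤ 200 ms (both inclusive); (4) within each participant ×
pleasantness × difficulty cell, trials with |z(RT)| > 3.5 (strict), using
moment-based z-scores from that cell's own mean and SD. Step 4's grouping
is by the two design factors, not by literal picture (one trial per
picture per participant would make per-picture z-scores degenerate); cells
with fewer than two trials or zero variance are skipped and logged. The
audit report records counts and percentages per step against the trials
remaining before that step.

## Reproduction sizes and numerical choices

The recovery analyses (and `scripts/acceptance.py`) use 12 subjects × 480
trials with the desk sampler profile — the package's chosen
simulation-study size, at which the population-location posteriors are
tight enough for a ±0.30 drift-unit recovery criterion and a single fit
completes in minutes on one core. Model-selection simulations use 5
subjects × 72 trials per fit with a further reduced profile (16 chains,
200 + 400, thin 2), which is sufficient for the DIC decision given the
large generating effects.

Other numerical choices: log-density floor −700; truncation handled by
inverse-CDF sampling; DE jitter SD 1e-3; quadrature tolerances follow
scipy defaults with the normalization identity checked to 1e-4; BANOVA
responses are standardized before analysis (the Bayes factors are scale
invariant; standardization keeps the default prior scales on their
intended standardized-effect reading).

## Known limitations

* R-hat on interacting DE chains is a practical diagnostic, not a proof of
  convergence; the ensemble shares information by construction.
* The aberrant drift for unpleasant stimuli (~0.017) is near-zero: those
  accumulators win a few percent of trials, so its subject-level posteriors
  are wide and population recovery leans on shrinkage. Recovered values
  can sit a tenth or two below truth at desk scale; the ±0.30 criterion
  absorbs this.
* DIC with posterior-mean plug-in is the comparison the workflow
  prescribes; it is not a substitute for marginal-likelihood comparison.
* Censored trials are flagged but the likelihood does not integrate over
  censoring; under the truncated convention and the default parameters the
  censored fraction is negligible, and the preprocessing window removes
  ≥ 6.1-s trials before fitting anyway.
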