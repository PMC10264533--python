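# Methods

## The decision model

Each speeded left/right decision is modelled as a Linear Ballistic
Accumulator (LBA) race. Two accumulators — one matching the stimulus, one
mismatching — start a trial at independent points drawn uniformly from
`[0, A]` and grow linearly at rates drawn from `Normal(v_i, s_v)`. The
first to reach the threshold `b` determines the response; the response
time is the winning passage time plus a nondecision offset `t0`.

The single-accumulator passage-time CDF and density use the standard
closed forms, with a dedicated branch for the degenerate `A -> 0` start
point. The joint ("defective") density of responding a particular way at
time `t` is `f_choice(t - t0) * (1 - F_other(t - t0))`. By default the
density is normalised by `1 - P(both drifts <= 0)`, matching a simulator
that redraws trials on which neither accumulator would ever finish; the
unnormalised variant remains available for cross-checks. Whether the
original analyses normalised this event is not documented anywhere we
could find; both modes are therefore exposed, with the normalised one the
default because it keeps simulator and likelihood exactly coherent.

Two facts about the LBA shaped several choices below:

* The raw passage time has a `t^-2` density tail, so its mean does not
  exist. Any quantity defined as a mean over raw LBA response times must
  be truncated to be well defined.
* Conversely, the survivor function of the race is just the product of
  the two accumulators' survivor functions, which gives the probability
  of any RT window in closed form — no quadrature.

## Truncation-corrected likelihood

The analysis pipeline excludes decisions with RT <= 250 ms or >= 5000 ms.
Fitting the plain LBA density to data filtered this way is a
misspecification: the excluded slow tail is precisely the part of the
distribution that carries information about small drift rates, and
ignoring the truncation biases the fitted rate sum upward by ~40% at this
study's parameters (we measured this directly in development: refitting
untruncated data recovered all generating group means; refitting
truncated data with the uncorrected likelihood covered 6 of 11). The
model therefore conditions each trial's density on the analysis window:

    log f_trunc(rt) = log f(rt) - log P(lo < RT < hi | params),

with the window mass computed from the closed-form race survivor. The
window is part of the model specification (`GroupModelSpec.rt_window`,
default `(0.25, 5.0)` s, `None` to disable) and the model refuses trial
tables containing RTs outside its window rather than silently misfitting.

## Hierarchical structure

For participant `p` in condition `c`:

* threshold `b_{p,c} = A_p + B_{p,c}` with condition-specific offset
  `B > 0` (this enforces `b >= A` by construction);
* drift rates from a shared rate sum and condition-specific rate
  difference: `v_correct = (s_p + d_{p,c})/2`, `v_error = (s_p - d_{p,c})/2`;
* `A_p`, `t0_p`, `s_p` shared across conditions; drift SD fixed at 1 for
  identifiability (the conventional scaling constraint).

Participant parameters follow normal group distributions, truncated to
positive support for `A`, `t0`, `s` and `B`; rate differences are
unconstrained. With the trait-competitiveness covariate enabled, the
participant-level mean of each condition's `B` and `d` gains a linear
term `beta * z_p` in the standardised trait score.

Default priors (all configurable): group means `A ~ N(0.5, 0.3) > 0`,
`B_c ~ N(0.5, 0.5) > 0`, `s ~ N(2, 1) > 0`, `d_c ~ N(1, 1)`,
`t0 ~ N(0.3, 0.15) > 0`; group SDs half-normal(0.3); slopes
`beta ~ N(0, 0.5)`. These are weakly informative on the scale of typical
LBA fits of perceptual two-choice data; the exact priors behind the
original analysis are not printed anywhere, so these defaults are this
package's own documented choice.

Condition effects are derived quantities: per posterior draw,
`db_c = mu_B[c] - mu_B[dyb]` (the shared `A` cancels, so this equals the
difference of group-mean thresholds) and `dd_c = mu_d[c] - mu_d[dyb]`,
with do-your-best the reference condition.

## Posterior sampling

No gradient-based probabilistic-programming stack is part of this
package's dependency set; instead the sampler is blocked
differential-evolution MCMC (DE-MCMC), the family most widely used for
hierarchical evidence-accumulation models, implemented vectorised over a
population of chains. Each iteration:

1. **Participant blocks.** One DREAM-style move per (chain, participant):
   a DE jump `gamma (x_r1 - x_r2)` restricted to a random subspace of the
   11 participant parameters (crossover fraction drawn from
   {0.4, 0.7, 1.0}), `gamma = 2.38 / sqrt(2 k)` for a `k`-dimensional
   update, occasionally `gamma = 1` for mode jumps. All proposals across
   chains and participants are evaluated in one fused numba pass over the
   trial table.
2. **Group blocks.** Given the participant blocks, the group posterior
   factorises over parameter types, so each `(mu_k, sigma_k[, beta_k])`
   pair is updated independently (several cheap sweeps; no likelihood).
3. **Non-centred group move.** A DE proposal on the whole group vector
   that carries every participant along through
   `theta' = loc' + (sigma'/sigma)(theta - loc)`, accepted with the
   deterministic-map Jacobian `P * sum_k log(sigma'_k/sigma_k)`. This is
   the move that crosses the group-mean/participant ridge and the
   `sigma -> 0` funnel, where purely centred updates stall.

Step-size multipliers adapt toward ~25% acceptance during warmup only
(Robbins–Monro, frozen afterwards). Chains initialise from a tight jitter
around one plausible point (with each participant's `t0` capped below
their fastest RT); the population then expands to posterior scale during
warmup. Convergence is summarised per parameter with rank-normalised
split R-hat and bulk ESS via arviz, warning at R-hat > 1.01 or ESS < 400
(community defaults; the original report contains no sampler settings).
On reduced-scale fits the weakly identified rate-sum/threshold ridge can
leave group-level R-hat around 1.1–1.4 at the chain lengths used in the
test suite; estimates and credible intervals for the reported quantities
are stable well before R-hat is clean, which the recovery studies verify
directly.

## Savage–Dickey Bayes factors

For a scalar effect with a point null at 0,
`BF = prior(0) / posterior(0)`: values above 1 favour a difference.
Densities at 0 come from a Gaussian KDE with Silverman bandwidth
(default) or a moment-matched normal; the prior density may be supplied
analytically where known (covariate slopes). KDE smoothing biases the
density a few percent upward when the null sits 2+ SDs into the
posterior tail; the conjugate-oracle tests document the size of this
error (≈7% at 2.5 SD, 1-D).

The joint analysis places equal prior probability on four nested models
of a `(db, dd)` pair — both null, threshold-only, rate-only, both free —
and converts Savage–Dickey density ratios into each model's marginal
likelihood relative to the both-free model (`w00` from the joint density
at (0,0); `wb`, `wd` from the marginals of the component pinned to zero;
`wbd = 1`). Reported Bayes factors are set odds, e.g. "threshold only vs
no effects or both" = `wb / ((w00 + wbd)/2)`. The original report
describes these comparisons only in prose; this construction is the
package's documented interpretation and is validated against an analytic
bivariate conjugate oracle, not against the original table's numbers.

Evidence labels follow the usual 1/3/10/30/100 bands (anecdotal,
moderate, strong, very strong, extreme), mirrored for evidence of no
difference.

## Synthetic experiment

The generator reproduces the structure of the competition study: 100
participants x 4 schemes x 15 episodes (6,000 episodes), points +1/-1
per correct/incorrect decision, a 1-s progress screen after every
decision, 20-s deadlines and/or 8-point goals per scheme, and an LBA
opponent in the tournament and race schemes.

Choices a scientist had to make, and why:

* **Deadline clock.** By default the 20-s deadline counts decision time
  only (the clock pauses during feedback screens). The alternative —
  charging feedback time — yields ~9 decisions per episode, while the
  design's totals (90,180 decisions over 6,000 episodes ≈ 15 per episode
  at ~1.2-1.3 s mean RT) are only consistent with the paused-clock
  reading. Both behaviours are exposed (`count_feedback`).
* **Censoring.** A decision still in progress at the deadline is not
  recorded and not scored. A tournament tie counts as a loss for the
  participant; an exact race tie resolves in the opponent's favour
  (conservative, measure-zero). All config-exposed.
* **Generating regime.** Group-mean thresholds 0.95/0.89/1.00/1.04 and
  rate differences 1.10/1.04/1.10/1.01 (dyb/tournament/race/igp) — the
  fitted values reported for the real data. `A = 0.30`, `t0 = 0.45` s
  and rate sum 1.6 were calibrated once so the do-your-best scheme shows
  ~77% accuracy and ~1.1-s mean RT with ~13-15 decisions per 20-s
  episode, then frozen.
* **Heterogeneity.** Threshold offsets decompose into a stable
  between-person caution component (SD 0.10) plus condition-specific
  deviations (SD 0.05). The decomposition is forced by arithmetic on the
  published interval estimates: at n = 100 a condition-difference CI of
  [-0.07, -0.04] implies a participant-level difference SD near 0.075,
  while the condition-mean CI [0.92, 0.98] implies a marginal SD near
  0.15 — impossible unless within-person thresholds are strongly
  correlated across conditions. Rate differences stay independent per
  condition (SD 0.18), which matches the published rate-difference CIs.
  Shared parameters: SDs 0.08 (A), 0.05 (t0), 0.25 (s).
* **Opponent.** One fixed LBA (b=1.6, A=0.3, v=1.55/0.45, t0=0.4 s;
  ~79% accurate, ~1.4-s decisions) plays every opponent episode,
  mimicking an opponent fitted once to pilot data. Its decisions are
  redrawn above 5 s — without a cap the mean time-to-goal does not exist
  (infinite-mean tail), and a human opponent's over-long responses would
  be lapses. Calibration: mean time to net 8 points = 19.9 s
  (Monte Carlo, n = 10^4), inside the intended ~20 s.
* **Competitiveness.** Scores are means of 14 five-point Likert items,
  each the participant's latent level (Normal(3.4, 0.6)) plus unit item
  noise, rounded and clipped; scores land in [1, 5] with a realistic
  spread (~0.6 SD).

What the generator does **not** emulate: the visual random-dot stimulus
(only its left/right answer and difficulty summary survive, as the
drift-rate means), practice episodes by default, within-episode strategy
adaptation, feedback-driven arousal, or contaminant processes (fast
guesses, attention lapses) other than the LBA's own tails. Passing
recovery tests therefore show that the pipeline is correct and well
calibrated for LBA-generated data of this design — not that the LBA is
the right model of any particular real dataset.

## Validation studies and problem sizes

The packaged studies (also exercised by the test suite and the
acceptance script) use sizes chosen to make each question answerable in
minutes on one core:

* **Parameter recovery** — 10 replications of 12 participants x 4
  episodes per condition (~2,800 decisions each) at the generating
  regime above; asserts >= 90% coverage of generating group means by 95%
  credible intervals. The qualitative result is unchanged at 20 x 5
  (verified during development).
* **Sign recovery** — one fit at 20 participants x 5 episodes:
  P(tournament threshold effect < 0) > 0.9.
* **Structure recovery** — 10 replications with a threshold-only
  tournament effect. The effect is set to one marginal SD (db = -0.15,
  all rate differences equal): the published effect (-0.06) is below
  what any method could reliably call at this scale, so the study tests
  structure identification at an identifiable magnitude. Asserts the
  "threshold only" joint BF is the largest of the four in >= 8/10
  replications.
* **Sampler contract** — exact targets (standard normal, correlated
  bivariate normal, a two-level conjugate Gaussian hierarchy with a
  closed-form posterior).
* **Estimator contract** — scalar and joint Savage–Dickey against
  conjugate closed forms (tolerances 8–10%, dominated by documented KDE
  tail bias).

## Numerical notes

* `A < 1e-10` switches the CDF/density to the degenerate-start closed
  form to avoid 0/0.
* Likelihood evaluations outside the support return `-inf` rather than
  raising, so samplers can reject.
* Densities below 1e-300 are treated as zero (log clamped).
* The fused numba likelihood kernel is bitwise-checked against the pure
  numpy reference implementation in the tests.
* RTs are seconds internally and milliseconds in every file format.

## Known limitations

* Episode deadline censoring (the in-progress decision cut at 20 s) is
  length-biased and not modelled in the likelihood; at this design's
  pace it is a ~5-7% trial-level effect with no measurable impact on
  recovery, but designs with far slower decisions would need an explicit
  censoring term.
* The joint Bayes-factor construction is one defensible reading of a
  prose description; published joint BFs are not a validation target.
* KDE-based Savage–Dickey degrades when the null sits far into the
  posterior tail (the BF is then effectively "very large" anyway; the
  `normal-approx` method and the reported densities help diagnose).
* Group-level R-hat on small LBA fits can exceed the 1.01 warning
  threshold along the rate-sum ridge; longer chains sharpen it, and the
  recovery studies bound the practical effect.
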