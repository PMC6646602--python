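# Methods

## The model

`secondsim` implements SECONDS (Socio-Emotional CONcern DynamicS), an
agent-based model of real-time dyadic play.  Each agent is described by five
coupled variables updated in discrete time (default step: 4 s, matching the
temporal resolution of observational coding systems; default session: 225
steps = 15 min):

* **Concerns** `(c_self, c_other)` — a preference pair for autonomy
  (self-directed play) vs relatedness (other-directed play) that always sums
  to one.  Concerns are initial conditions that drift slowly within a session
  through emotional reinforcement.
* **Concern realization** — an appraisal of how well the session so far
  matches the concerns.  With `r` the realized joint-play proportion
  (memory count / steps) and `d = c_other − r`, the appraisal score is
  `−a3·|d| + ω` and a compensatory drive of magnitude `a3·|d|` points toward
  other-directed play when `d > 0` and toward self-directed play when
  `d < 0`.  ω is zero-mean Gaussian noise (sd 0.05 by default), drawn
  independently per agent per step from a single seeded generator.
* **Play behavior** — self- or other-directed, drawn from a normalized
  other-directed propensity
  `π = [a4·g(drive) + a5·1(own prev = other) + a6·1(partner prev = other) +
  baseline·c_other] / (a4 + a5 + a6 + baseline)`, with
  `g(drive) = (1 + signed drive)/2 ∈ [0, 1]`.  The draw is Bernoulli so
  session outcomes vary continuously across runs; a hard argmax produces
  degenerate all-or-nothing sessions.
* **Emotional expression** — negative/neutral/positive (−1/0/+1), from a
  thresholded latent affect `u = a7·score + a8·prev_own + a9·prev_partner +
  ω`, with symmetric default thresholds ±0.3 (expression thresholds are known
  to vary between children; the default is a neutral middle band wide enough
  that sub-threshold noise alone essentially never triggers an expression).
* **Memory** — the accumulated count of joint-play outcomes
  `z_t = AND(both other-directed)`.

Only behavior and emotional expression are observable to the partner.  Both
agents update synchronously from the partner's previous-step observables, so
agent order carries no information; within a step the order is: bank the
previous joint outcome into memory, appraise, choose behavior, choose
emotion, update concerns.  At the session start there is no history, so the
realized proportion is defined as `c_other` itself (no spurious initial
drive), initial behaviors are drawn from each agent's initial concerns, and
initial emotions are neutral.  An exact `d = 0` tie yields no drive.  If all
four behavior weights are zero there is no propensity to normalize and the
previous behavior persists (frozen dynamics).

For emotional symmetry the model couples to the *partner's previous emotional
expression* (contagion), matching the mechanism's semantics; an alternative
reading couples it to the partner's behavior instead.

## The ASD child and the two parents

The child preset encodes three deviations from a typically developing child
(`c_other ≈ 0.70`): balanced concerns (`c_other = 0.50`), weakened emotional
processing and communication (lower `a2, a3, a7`), and a shift from imitation
to repetition (higher `a5, a8`; lower `a6, a9`).  The same child is shared by
both shipped dyads.

Parents keep the child architecture and add four implicit strategy
mechanisms: scaffolding (their relatedness concern is clipped above an
estimate of the child's — a floor at the child's *initial* concern 0.50 for
the play-centered parent, a band (ref+0.01, ref+0.15) for the
initiative-centered parent), selective symmetry (`a6` conditional on the
child's previous behavior), selective satiation (`a3` per concern), and a
selective emotion policy (suppress negative; encourage the child's
other-directed play with positive expressions; the play-centered parent
additionally withholds positive expressions while the child plays alone —
withheld expressions become neutral, never negative).  Because the child's
concern is hidden, the scaffolding reference defaults to the running mean of
the child's observed other-directed behavior (initialized at the child's
initial concern); a configuration switch (`use_true_child_concern`) allows
the true concern as a simulation shortcut.

Satiation semantics: the drive that arises while a concern is in *surplus*
is scaled by that concern's sensitivity.  `a3_relatedness < a3_autonomy`
therefore means joint play beyond the concern level is barely corrected
(relatedness satiates slowly), biasing the parent toward joint play.

## Calibration of the shipped defaults

The per-mechanism weights have no published values — only qualitative
constraints (which parameters are relatively low/high, which strategy is
more selective).  The shipped defaults were calibrated against the published
across-session reference table (medians and 95% CIs of seven summary
variables over 2,000 sessions per dyad) under those constraints, using a
seeded stochastic search on batches of 300–2,000 sessions.

The calibration cannot reproduce every published interval, and the reason is
structural, not numerical.  In stationarity the additive propensity makes an
agent's other-directed play fraction a weighted mean of three terms —
`g(drive)`, the partner's other-directed fraction, and `c_other` — none of
which can fall below ~0.5 for the shared child (its concern never drops
below 0.5 and its relatedness drive stays unmet), while the reference table
implies child other-directed fractions near 0.40–0.46.  Likewise the
initiative-centered parent's published profile (soliciting twice as much
time as spent in mutual solitary play) requires a conditional other-directed
propensity above any of its bounded components given the "fairly strong"
symmetry the strategy prescribes.  The original model's unpublished
functional forms evidently differ in ways the simplified additive forms
cannot mimic; the calibrated defaults honor all qualitative ordering
expectations and land as close to the published intervals as the form
allows.  The corresponding acceptance test is left failing rather than
weakening the published tolerances or the qualitative constraints.

## Summaries and validation

Each step is classified as `together`, `alone`, `attempt_child`, or
`attempt_parent` from the two behaviors.  Because observed coding registers
only verbalized initiation attempts, single-step attempt runs (< 8 s) are
recoded as `alone` — the observer sees no verbal initiation, so both members
appear to play alone.  A `together` episode immediately preceded by an
attempt is credited in full to the attempting agent (`success_child` /
`success_parent`); a together episode entered directly from `alone` is
unattributed, and an attempt that flips directly into the other agent's
attempt breaks adjacency (the later attempt gets the credit).  A minimum
together duration of one step counts as success; this is configurable in
principle but not exposed as a preset.  Batch tables report medians with
percentile bootstrap 95% CIs of the median (B = 10,000, seeded); the CI
method for the published table is unstated, so the bootstrap is a
documented package choice.

The validation layer estimates across-session densities of the six
time-allocation variables on proportions in [0, 1] (not percentages — the
divergence of continuous densities is scale-dependent; the unit interval is
the documented choice) with a Gaussian-kernel KDE: Silverman bandwidth,
boundary reflection at 0 and 1 (sessions with exactly zero time in a state
keep their mass), a 512-point shared grid, a density floor of 1e-9, and a
fallback bandwidth of 0.01 for numerically constant samples.  Divergences
are trapezoid-quadrature `KLD(observed ‖ candidate)` in nats, additive over
the six variables.  The beta reference null is mean-matched with `α = 1`
(the weakest-information shape consistent with the stated means: `β = 3`
for mean 25%, `β = 7` for mean 12.5%).

The published evidence formula `p0 = e^KLD0/(e^KLD0 + e^KLD_model)`
*increases* with the null's divergence, contradicting its description as the
null's likelihood; the sign-corrected variant
`e^−KLD0/(e^−KLD0 + e^−KLD_model)` decreases.  Neither reproduces the
published p-values from the published divergences, so both are reported
side by side and clearly labeled; no intent is guessed.

## Synthetic fixtures

Real coded corpora of this kind are not publicly deposited, so the package
generates synthetic event-coded sessions: a semi-Markov chain over the four
states with geometric episode durations (attempts shifted to a minimum of
two steps so fixtures survive the verbalization filter) and transition
weights fixed-point-adjusted so long-run occupancy matches requested target
proportions.  Defaults (29 sessions of 225 steps; occupancy 40/30/10/20%;
mean episodes of 5/4/2.5/3 steps) emulate the scale and block structure of a
real free-play corpus.  The generator emulates occupancy and episode
persistence only — it has no agent dynamics, no within-session
non-stationarity, and no coupling between states beyond the embedded chain —
so pipeline tests built on it demonstrate statistical machinery, not
behavioral realism.

## Problem sizes and numerical choices

Full-scale runs use the published scale (2,000 sessions x 225 steps per
dyad, ~10 s each on one CPU); unit tests use smaller batches.  The pipeline
self-check compares 29-session pseudo-observations (the observed corpus
size) against the 2,000-session candidate over repeated held-out seeds.
Per-session seeds are derived from the master seed by a counter-based
sequence, so batches are order-independent and any session can be re-run in
isolation.  All stochastic tests are seeded; KDE grids are shared between
densities before any divergence is computed, and a divergence of a density
with itself is exactly zero.

## Known limitations

* Single sessions only: no between-session carry-over of concerns.
* One relatedness dimension: affection ("cuddling") is not modeled,
  matching the free-play focus.
* Emotions are a single three-level channel; verbal and non-verbal
  initiation are not distinguished beyond the two-step verbalization rule.
* The simplified additive update forms cannot reproduce every published
  across-session median (see Calibration above); they reproduce the full
  qualitative ordering structure and the pipeline-level statistics.
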