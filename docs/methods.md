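# Methods

## The experiment being modelled

`selfmotion` simulates and analyzes two-alternative forced-choice (2AFC)
direction-discrimination experiments in which a brief inertial movement —
lateral sway translation or yaw rotation — is judged as leftward or
rightward while a visual stimulus (a moving star field, a static illusory-
motion image, or a directional arrow) biases the percept. The scientific
statistic of interest is the *point of subjective equality* (PSE): the
signed stimulus magnitude at which both reports are equally likely. A
left-directed versus right-directed visual condition pair is summarised by
the difference of the two PSEs; a negative left-minus-right difference
means the perceptual bias is opposite the direction of visual motion, the
signature of visually induced self-motion (vection).

## Inertial stimulus

The movement is one full cycle of sinusoidal acceleration over duration
`T` (default 1 s):

    a(t) = A sin(2πt/T),   A = 2πD/T²

where `D` is the total displacement (cm for sway, degrees for yaw). This
is the unique single-cycle waveform with continuous acceleration, velocity
and position; position runs monotonically from 0 to `D` and the peak
velocity is `v_peak = 2D/T`. A nominal "0.5 Hz" frequency label is
sometimes attached to such 1 s movements; since a true 0.5 Hz cycle lasts
2 s, the label is stored as metadata only and the waveform is always one
full cycle over `T`. All analysis magnitudes are signed peak velocities
(cm/s or deg/s); staircase parameters are specified in the displacement
domain (platform limits ±10 cm or ±10°, i.e. ±20 velocity units at
`T` = 1 s).

## Adaptive staircase

Each visual condition is measured by a 25-trial 1-up/1-down staircase
starting at the platform maximum with an initial step of 4 displacement
units:

* after each counted response the magnitude moves by the current step
  *opposite* the response (so the series brackets the PSE and may cross
  zero);
* the step halves on a response reversal (L→R or R→L within the same
  staircase), floored at 0.25;
* the step doubles whenever the last three counted responses share a
  direction, capped at 4; a fourth identical response re-triggers the
  doubling. The trigger re-arms after any differing response.
* step adaptation precedes the magnitude move; this ordering is pinned by
  the worked example 10 cm → (response "right") → 6 cm.
* magnitudes are clamped at the physical platform limit rather than
  raising.

Timed-out trials (response NONE, probability `p_none`, default 0.5%) are
logged as events but never counted: the staircase state is unchanged and
the same magnitude is re-presented later, so counted totals are always
25 per staircase.

Experimental blocks interleave two independent staircases (left-visual and
right-visual), each starting at the maximum on the side of its own visual
condition; the presenting staircase is chosen uniformly at random among
the incomplete ones, except that a run of more than `max_run = 5`
same-direction stimuli is broken by switching to the other staircase when
possible. If neither staircase can break the run the trial is presented
anyway and flagged `run_violation`, preserving auditability. Control
blocks are a single 25-trial staircase.

Convergence: against a noiseless responder with PSE inside the range, the
mean of the final 10 presented magnitudes lies within 0.25 velocity units
of the PSE (bounded in tests by twice the final step size).

## Synthetic observer and cohort presets

An observer reports RIGHT with probability
`λ/2 + (1−λ)Φ((v−μ_c)/σ)`, with per-condition PSE `μ_c`, axis-specific
width `σ`, and lapse rate `λ` (default 0; available because forced-choice
guessing can manifest as stimulus-independent errors). Cohorts draw, per
subject: `σ` from a truncated normal (defaults: mean 1.1, SD 0.6 sway /
0.7 yaw, floor 0.2 — velocity units); an idiosyncratic axis baseline bias
(SD 0.5 cm/s sway, 1.0 °/s yaw) added to every condition of that axis, so
it cancels in left-minus-right differences; and a per-block-type effect
from `N(mean, SD)`, split evenly as `baseline ± effect/2` between the
left- and right-visual conditions.

Default generative effect means (left-minus-right PSE difference) are the
study-scale presets: −0.832 cm/s (sway star field), −3.394 °/s (yaw star
field), +0.508 cm/s (arrow), and 0 for both illusory-motion block types
(their reported differences are small with p > 0.1, i.e. treated as null).
Between-subject effect SDs (0.5 cm/s sway, 1.5 °/s yaw) are not published
quantities; they were chosen once to match the visual spread of
per-subject estimates and are documented here rather than fitted.

What the generator does *not* emulate: vection onset latency and the 8 s
viewing interval, within-block drift of the bias (observers are
stationary), order/learning effects, and inter-stimulus correlations.
Passing recovery tests therefore shows the analysis chain is consistent
with its own generative model at study scale — not that real subjects
satisfy that model.

## Psychometric fit

`P(RIGHT | v) = λ/2 + (1−λ)Φ((v−μ)/σ)` is fitted by maximum likelihood
over `(μ, σ)` with `λ` fixed. The optimizer is a bounded quasi-Newton
(L-BFGS-B) search with analytic gradients from five deterministic starts
(a moment-based start and four perturbations); ties are broken by best
likelihood, then smaller `σ`. `σ` is bounded below by a configurable
floor (default 0.01 stimulus units). With `λ = 0`, perfectly separable
data have no finite MLE; such fits are flagged `degenerate` and return
the midpoint of the separating gap as `μ̂` with `σ̂` at the floor. The fit
is exposed as a scikit-learn estimator (`fit` / `predict_proba` /
`get_params`) so it composes with sklearn tooling; equivalence with an
exhaustive 200×200 grid search and with an independent probit regression
(μ = −β₀/β₁, σ = 1/β₁) is pinned in tests.

## Bootstrap and comparison

PSE uncertainty is quantified by a nonparametric bootstrap: trials are
resampled with replacement (same n), refitted, and the resampled `μ̂`
collected (default 2000 replicates; a 100-replicate variant is supported
but cannot resolve p-values below 0.02). Confidence intervals
are percentile intervals (2.5th/97.5th), with no BCa correction.
Bootstrap refits with `λ = 0` are solved by a Newton iteration on the
probit parametrisation `Φ(a + bv)` — the log-likelihood is concave in
`(a, b)` — batched across replicates for speed; replicates the batch
solver cannot certify fall back to the canonical multi-start optimizer,
and agreement between the two solvers is property-tested (≤ 2·10⁻⁴).
Separable replicates contribute their gap-midpoint estimate and are
counted; non-converged refits are dropped and counted, with an error if
fewer than half succeed.

Two conditions of one block are compared by the Monte Carlo difference
distribution: index-paired resampled differences `d_i = μ̂L,i − μ̂R,i`,
`p = 2·min(f, 1−f)` with `f = P(d < 0) + ½P(d = 0)` (ties split so that
identical distributions give p ≈ 1) and a continuity floor `1/(N+1)`.
The reported difference is the difference of bootstrap means.

Group level: the primary statistic is the arithmetic mean of per-subject
differences per block type, with a subject-level bootstrap (10⁴ draws of
subjects with replacement, same two-sided rule) for the group p-value and
CI. Threshold summaries pool non-degenerate `σ̂` per axis. With a single
subject the group p is reported as undefined.

## Numerical and design choices

* All randomness flows through explicit `numpy.random.Generator` seeds;
  analysis sub-seeds derive from a stable hash of (subject, block,
  condition) so results are independent of iteration order.
* Probit tail quantities use log-space CDFs (`log_ndtr`) for stability;
  probabilities are clipped at 10⁻¹² inside likelihoods.
* Degenerate inputs (empty trial sets, single-class responses, σ ≤ 0,
  lapse ≥ 0.5) raise or flag as documented in the API, never silently.
* Simulation sizes in the test-suite and acceptance script (e.g. 400–1000
  zero-effect blocks, 300 coverage datasets, 200–2000 bootstrap
  replicates) are the package's own choices balancing Monte Carlo error
  against runtime on a single CPU; each reported rate carries its `n`.

## Measured limitations

These are properties of the method under the experiment's own design,
measured by this package's simulations and left visible rather than
tuned away:

* **Threshold bias.** The MLE `σ̂` from 25-trial staircase data is biased
  low by a roughly constant factor ≈ 0.7 (measured across seeds and both
  axes): 1-up/1-down sampling concentrates trials near the PSE, which is
  efficient for `μ` but starves the likelihood of information about the
  slope. Cohorts generated with σ ≈ 1.1 recover pooled mean `σ̂` ≈ 0.75–
  0.9, outside the ±0.2 recovery band. Fixed-level designs at the same n
  recover σ nearly unbiasedly (≈ 1.0), confirming the cause is the
  adaptive design, not the optimizer.
* **Anticonservative bootstrap on adaptive data.** The same mechanism
  makes the nonparametric bootstrap underestimate the sampling spread of
  `μ̂` on staircase data: the zero-effect block comparison rejects at
  ≈ 9–12% instead of the nominal 5%, and the 95% percentile CI covers the
  generative PSE ≈ 89% of the time. On i.i.d. constant-stimuli datasets
  of the same size the identical machinery is calibrated (type-I ≈ 5%,
  coverage ≈ 93%). Per-subject significance flags from staircase blocks
  should therefore be read as liberal; group-level conclusions rest on
  the subject-level bootstrap, which does not inherit the within-subject
  undercoverage.
* Percentile intervals (as specified) slightly undercover even in the
  i.i.d. case at these sample sizes (≈ 93% vs 95%); BCa or basic
  intervals were deliberately not substituted.
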