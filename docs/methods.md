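# Methods

## The task and its generative model

The package models a two-stage random-dot motion experiment.  On a
*double-decision* trial the observer judges motion direction twice in
sequence (left/right, then up/down at the chosen target) and is rewarded
only if **both** choices are correct; a confidence rating (0–1) follows the
final choice.  Three single-decision types are interleaved: `D1star`
(first decision only, rated), `D2star` (first decision bypassed, second
decision only, rated), and `D1catch` (looks like a double trial but stops
after the rated first decision).  Signed coherences come from
{0, ±0.032, ±0.064, ±0.128, ±0.256, ±0.512}; a block holds all 121 ordered
coherence pairs as double trials plus 11 trials of each single type (154),
and a session holds four blocks — base, mirror (signs and rewarded
directions flipped), and independently re-shuffled repeats of both.  The
default experiment is 9 sessions (5,544 trials).  Inter-event delays are
drawn from an exponential distribution truncated to [0.3, 1.0] s whose rate
is solved numerically so the truncated mean is 0.57 s.

Decisions are generated by a drift-diffusion process: evidence accumulates
from zero with drift `kappa * (C + C0)` and unit variance per second until
it hits `+B` or `-B`.  Reaction time is the decision time plus a fixed
non-decision time `tnd`.  The first decision uses bound `B1` scaled by a
per-session factor; the second uses `B2 = (b0 + b_conf * conf1) * scale`,
where `conf1` is the agent's internal confidence in the first decision
(1 on `D2star` trials, where there is nothing to be uncertain about).

### Agent confidence

Confidence is the Bayesian posterior probability that the chosen direction
is rewarded, given the crossed bound, the decision time, and a short
post-decision evidence sample, under the known uniform prior over the 11
signed coherences.  Two closed-form facts make this cheap:

* the two-boundary first-passage density factorizes as
  `exp(s·mu·B − mu²t/2) · f0(t, B)` with `f0` independent of the drift, so
  the drift-independent factor cancels in the posterior over coherences;
* a post-decision evidence sample `y ~ N(mu·tau, tau)` contributes
  `exp(y·mu − mu²·tau/2)`.

The posterior mass on coherences whose sign matches the choice, plus half
the mass on zero coherence (rewarded by a fair coin), is the confidence.
The post-decision window (default `tau = 0.2 s`) represents stimulus
information in the processing pipeline that arrived too late to affect the
choice; it makes confidence lower on errors than on correct choices at the
same coherence and RT, as observed empirically.  Recorded ratings add
Gaussian noise (sd 0.08 on the 0–1 scale, clamped) to the internal
confidence — on double trials to the product of the two stages'
confidences, since the rating concerns the conjunction.

### Default agent parameters

| parameter | default | meaning / why |
|---|---|---|
| `kappa` | 10 /s per unit coherence | ~65% accuracy at 3.2%, ceiling at 51.2% |
| `C0` | 0 | no choice bias |
| `tnd_s` | 0.35 s | typical saccadic non-decision time |
| `B1` | 1.0 | ~1.35 s mean RT at 0% coherence |
| `b0`, `b_conf` | 0.5, 0.85 | second bound rises ~25–35% over the range of *estimated* confidence (the k-NN estimates compress the latent range, so the effect is calibrated on the scale the analysis actually sees) |
| `session_bound_scale` | 9 factors within ±8% of 1 | day-to-day criterion drift |
| `rating_noise_sd` | 0.08 | ratings are imperfectly reliable |
| `pde_duration_s` | 0.2 s | post-decision evidence window |

## Numerics of the diffusion engine

Choice probability and mean decision time use the standard closed forms
`P(+B) = 1/(1+exp(−2·mu·B))` and `E[T] = (B/mu)·tanh(mu·B)` (`B²` at
`mu = 0`, with an explicit branch below `|mu·B| = 1e-8` for continuity).
The Monte-Carlo engine is Euler–Maruyama with Gaussian increments.  A
discrete-time walk checked only at grid times systematically overshoots the
first-passage time by O(√dt); the engine therefore applies the
Broadie–Glasserman–Kou continuity correction (the absorbing boundary is
pulled in by `0.5826·√dt`), which reduces the bias to O(dt).  Without this
the mean-time bias at the validation grid (dt = 1e-4 s, n = 1e5) would
exceed three Monte-Carlo standard errors; with it, analytic and simulated
values agree within sampling noise.  Simulation of behavioral datasets uses
dt = 1e-3 s.

## k-NN confidence interpolation

Double-decision first decisions are assigned the mean rating of the k
single-decision trials (`D1star`/`D1catch`) with the same unsigned
coherence and accuracy whose RTs are closest (k = 30 correct, k = 15
error; errors are rarer).  Zero-coherence decisions are grouped with the
correct class.  RT-distance ties break deterministically by (distance, rt,
insertion index).  Leave-one-out cross-validation on the rated trials
reports the fraction of rating variance the rule explains.  Cells smaller
than k raise by default; the pipeline-level annotation uses a `shrink`
policy (all available entries; nearest coherence for an empty cell) because
errors at the strongest coherences are too rare to fill a 15-entry cell —
the same shortfall any faithful dataset of this design exhibits.  Signed-
coherence matching is available behind a flag but unsigned is the default:
signed error cells would be even smaller.

## Model fitting

Only second decisions (`D2nd` of double trials, plus `D2star` with
confidence fixed at 1) are fit.  The likelihood is Bernoulli in every
choice via `P(+B)` above, plus a Gaussian term for the reaction times of
*majority* trials: the model's predicted mean RT with the **empirical**
per-(session, unsigned-coherence) standard deviation of majority-trial
RTs.  Majority trials are found by a 2-parameter logistic of choice on
signed coherence (point of subjective equality), falling back to the
sign-of-coherence rule under separation.  Restricting the RT term to
majority trials reflects the flat-bound model's known failure to capture
error RTs; a flag extends it to all trials.

Six variants vary the bound B and sensitivity kappa: by session, and/or
linearly in the (mean-centered) confidence covariate — M1 (B by session),
M2 (kappa by session), M3 (M1 + bound slope), M4 (M2 + kappa slope),
M5 (B by session, kappa slope), M6 (kappa by session, bound slope).  C0 and
tnd are always shared.  Degrees of freedom follow directly from this
parameterization.  Optimization is box-constrained L-BFGS-B from a
moment-based start plus dispersed restarts (bounds: kappa ∈ (0.01, 100],
B ∈ (0.01, 10], C0 ∈ [−0.2, 0.2], tnd ∈ [0, min RT)); a non-positive
effective bound returns a large smooth penalty rather than an exception.
Models are compared by `BIC = df·ln(n) + 2·NLL`, and across subjects by
summing df, n, and NLL.  Standard errors come from the numerical
(central-difference) Hessian at the optimum.  The confidence covariate can
be swapped for unsigned first-decision coherence with one flag (`D2star`
trials then take the strongest coherence, the analogue of confidence 1).

Two further estimators probe the bound–confidence link without assuming
linearity: a fit with an additive bound offset per confidence quantile
(lowest quantile as reference; percent change reported relative to the
average session bound on lowest-quantile trials), and the zero-coherence
estimator `B̂ = sqrt(mean RT − tnd)`, valid because `E[T] = B²` at zero
drift.  With ~680 trials per quantile the offset standard errors (~0.035)
exceed adjacent-quantile differences of the generative effect, so the
quantile estimates scatter around the linear relation rather than rising
strictly monotonically; validation therefore checks the trend (no adjacent
decrease beyond 2 SE, top minus bottom positive beyond 2 SE, all offsets
within 2 SE of the weighted linear fit).

## Model recovery

For each generating model, synthetic datasets are produced on the real
trial scaffold (sessions, coherences, interpolated confidences) from the
model's fitted parameters, by simulating the diffusion per trial; all six
variants are refit to each dataset and the BIC winner recorded.  Defaults
are desk-scale (20 datasets per generating model, 2–3 optimizer restarts);
counts are configurable.  Fit failures count as "no winner" and are
reported, never dropped silently.

## Normative bounds by dynamic programming

The second decision is treated as optimal stopping on the belief state
(accumulated evidence x, elapsed time t), with the signed coherence drawn
from the known prior.  Because the path likelihood ratio between drifts
depends only on the endpoint, the posterior over coherences given (x, t)
is closed-form even though paths are censored by the policy.  Stopping
yields `conf1 · R · P(best choice correct | x, t)` — the trial pays only
if the first decision (correct with probability `conf1`) and the second
are both right.  Time is charged either at a fixed cost per second or at
the reward rate rho, with rho solved (Brent's method, tolerance 1e-6) on
the average-reward fixed point: the value of starting a decision equals
`rho · (tnd + iti)`, the opportunity cost of the dead time a trial entails.

One subtlety: everything in the stopped value scales linearly with
`conf1`, so a rho solved separately per confidence level would make the
optimal bounds *identical* across levels.  The reward rate is a property
of the whole task, not of one confidence level; `solve_bound_family`
therefore calibrates a single rho on the equal mixture of the requested
levels and derives each level's bounds at that shared rate.  Under either
cost structure, higher `conf1` then acts like a lower effective time cost
and raises the bounds — mostly as a vertical offset, with little change in
shape.

Backward induction runs on a (time × evidence) grid — defaults dt = 5 ms,
horizon 5 s, evidence ±5 in 201 points, uniform prior over the 11
coherences, R = 1, tnd = 0.35 s, iti = 2 s — with row-normalized discrete
Gaussian transition kernels per coherence.  The bound at each time is the
smallest |x| where stopping is optimal.  With the 11-coherence prior the
continuation region closes only asymptotically (the weakest coherences
separate on a ~20 s timescale), so the horizon check verifies instead that
the unabsorbed probability mass at t_max, computed by forward propagation
under the extracted policy, is below 1e-4.  Policy simulation uses the
same continuity-corrected absorbing boundary as the flat-bound engine.

## What the simulator does and does not emulate

The generator reproduces the trial design exactly (block composition,
mirroring, session structure, delays) and the statistical structure the
analysis assumes: bounded-accumulation choices and RTs, confidence that
rises with coherence and falls on errors, and a second-decision bound
linear in first-decision confidence.  It does not emulate: non-decision
time variability (RT dispersion at fixed coherence is decision-time
dispersion only, since the fits take RT SDs from the data), lapses,
sequential (trial-history) effects, slow non-stationarities within a
session, collapsing bounds in the *behaving* agent, or any rendering/
oculomotor detail.  Passing tests therefore show that the pipeline
recovers what it assumes from data of this structure — not that real
observers satisfy those assumptions.

## Problem sizes

Validation runs use: the full 9-session design (4,752 second decisions)
for parameter recovery and the quantile fit; 20 synthetic datasets per
generating model for model recovery; n = 1e5 paths per grid point
(dt = 1e-4 s) for the analytic-vs-Monte-Carlo checks; n = 1e4 trials for
the zero-coherence estimator; and 3,000 paths per coherence per confidence
level for the normative policy simulations.

## Known limitations

* The Gaussian-RT likelihood with empirical SDs is a working
  approximation, not a full first-passage-density likelihood; error-trial
  RTs are deliberately excluded from the RT term by default.
* The k-NN interpolation inherits attenuation: extreme internal
  confidences regress toward their cell means, compressing the covariate
  range relative to the latent variable.
* The dynamic program optimizes the second stage only, for a given
  `conf1`; joint optimization of both stages (and of the first-stage
  policy's effect on the confidence distribution) is out of scope.
* BIC comparisons assume equal prior odds across the six variants and
  n-dominated penalty; no hierarchical or Bayesian estimation is provided.
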