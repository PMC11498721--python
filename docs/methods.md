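# Methods

## The model

`sfcpitch` simulates online control of voice fundamental frequency (f_o)
under a state feedback control (SFC) architecture, and fits that model to
group-average responses to auditory pitch perturbations.

**Plant.** The larynx is idealized as a damped spring-mass system whose
spring rest length is linearly related to produced pitch, so the position
state is read directly in cents of f_o deviation from baseline:

    A = [[0, 1], [−k/m, −b/m]],  B = [[0], [k/m]],  C = [[1, 0], [1, 0]]

with k/m = 160000 and b/m = 1600 held fixed throughout (these anatomical
constants are not fitted).  A command integrator (continuous-time A = 0,
B = 1, C = 1) sits in series *upstream* of the spring-mass system: the
controller emits rate commands whose integral drives the plant input.  The
series system is assembled as one 3-state continuous model and discretized
exactly by zero-order hold at dt = 0.004 s, giving 300 frames per 1.2 s
trial.  The source description of the cascade ordering is ambiguous
(the integrator both "precedes" the main system and "produces a position
from its output"); we adopt the upstream reading because it yields a
well-posed SISO cascade in which the spring-mass position is the
pitch-determining state, and we keep the downstream alternative behind a
config/constructor flag (`integrator_upstream=False`) for comparison.
Note the cascade necessarily carries the integrator's exact unit
eigenvalue in `Ad`; the closed loop, not the open-loop plant, is the
stable object.

**Loop.** Each frame runs: control u = g_c·(x_target − x_estimate) on the
position component (x_target ≡ 0 for the sustained-vowel hold task) →
plant update with isotropic process noise (variance σq = 1e-8 per state
element) → two-channel sensory feedback y = (y_a, y_s), both channels
sensing the produced pitch, with independent Gaussian measurement noise of
variance σa = σ = 10^sigma_log10 (auditory) and σs = σ/r (somatosensory) →
the perturbation addend (−100 cents on the auditory channel only, for
0 ≤ t < 400 ms) → observer update.  The observer predicts the state from
an efference copy of the previous command, predicts feedback through the
same plant model, and corrects with per-channel prediction errors
evaluated at each channel's own delay:

    y_error[ch] = y[t − Δch] − y_predicted[t − Δch],  x_error = K·y_error

Both terms share the delay index (the literal reading of the update rule);
histories are zero-padded before trial start.  Delays are converted from
ms to whole frames by nearest-integer rounding and must round to ≥ 1 frame
(so delta_s as low as the 3 ms prior bound is valid on the 4 ms grid, but
values under 2 ms are "invalid" — below the frame rate of the model).

**Kalman gain.** K is the steady-state gain K = P̂Cᵀ(CP̂Cᵀ + R)⁻¹ with P̂
solving the estimation-form discrete algebraic Riccati equation for
(Ad, Cd, Q = σq·I₃, R = diag(σa, σs)).  The printed source equations mix
the control- and estimation-form DAREs and are dimensionally inconsistent
as a product; the estimation form with the innovation covariance sum is
the only consistent reading and is what we implement.  Delays live in
history buffers outside the state equations, so the gain is optimal with
respect to the delay-free model — this is deliberate and matches the
original analysis.  Because inference evaluates tens of thousands of noise
parameterizations, gains are computed in batch with a
structure-preserving doubling iteration (quadratically convergent;
validated against `scipy.linalg.solve_discrete_are` and against a
brute-force Riccati recursion in the tests; entries that fail a residual
check fall back to the scipy solver).

**Reported output.** Produced pitch is the noiseless auditory mapping of
the plant state (Cd·x, auditory row); measurement noise and the
perturbation addend affect only the feedback loop, never the report.  A
run whose |f_o| exceeds 1e4 cents — far outside physiology — is flagged
unstable; consumers decide (training sets resample, sensitivity sweeps
report "unstable", mean responses exclude and count).

There are two simulator implementations: a per-step reference loop built
from the named operations and a vectorized batch path (plant matrices are
shared across trials; only K, delays, gain and noise scales vary).  They
consume identical noise streams and agree to round-off; tests enforce
this.

## Inference

Inference is simulation-based: θ = (Δa, Δs, log10 σ, r, g_c) is drawn from
independent uniform priors (Δa ∈ [50, 200] ms, Δs ∈ [3, 80] ms,
log10 σ ∈ [−6.5, −3], r ∈ [0.1, 6], g_c ∈ [0.1, 8]), one trial is
simulated per draw, and i.i.d. per-frame U(−3.5, 3.5) cents noise is added
to training outputs (regularizing the near-deterministic simulator).
Unstable draws are resampled and counted.  Two interchangeable backends
approximate p(θ | observation):

- **rejection ABC** — keep the `accept_quantile` fraction of training
  draws closest to the observation in pointwise trajectory RMSE (the same
  metric used for fit quality), then resample to the requested posterior
  size.  Deterministic given seeds, assumption-free; the work-horse for
  testing.  An optional local-linear regression correction (Beaumont-style:
  ridge regression of θ on whitened PCA trajectory features over the
  accepted set, Epanechnikov-weighted by distance, each draw shifted to the
  observed feature point and clipped to the prior box) removes most of the
  tolerance-induced shrinkage of point estimates; pinned parameters are
  unaffected because their degenerate prior box clips them back exactly.
- **mixture-density conditional estimator** — PCA-compress trajectories
  (15 whitened components), standardize θ, fit a full-covariance Gaussian
  mixture (8 components) to the joint vectors, and condition analytically
  on the observed features; sampling rejects draws outside the prior box.
  This is the conditional-density route (the original analysis used a
  neural posterior estimator; a Gaussian-mixture conditional is the
  classical equivalent and needs no deep-learning stack).

The procedure is repeated (independent training set and backend per
repetition, seeded as seed + repetition id) and samples are pooled.  The
per-parameter pooled median is the "inferred value"; equal-tailed 95%
credible intervals and SDs summarize the marginals.  Groups are compared
with Glass's delta — (mean_A − mean_B)/SD_B, the control group being B —
as mean ± SE over 100 bootstrap resamples of size 1000.  Two hypotheses
are read off the pooled medians: H1 (greater relative auditory reliance
in the clinical group): r_CA < r_control; H2 (greater reliance on feedback
overall): σ_CA < σ_control.

### Budgets

Full-scale defaults mirror the original analysis: 10^5 training
simulations, 10^4 posterior samples, 10 repetitions, density backend.
Two reduced presets are used by the test and acceptance suites:

- `desk_scale()` — 2×10^4 sims, 3 repetitions, ABC at the 1% quantile.
  Used for parameter-recovery checks, where wide-but-calibrated
  posteriors are exactly what is being tested.
- `headline_scale()` — 6×10^4 sims, 3 repetitions, ABC at the 0.2%
  quantile with the local-linear regression correction (below).  Used for
  the group-comparison and ablation studies.  The
  driver here is accuracy of the *point* (median) estimates: a
  distance-landscape analysis around the packaged ground truths shows
  ±0.3 in log10 σ or ±0.5 in r/g_c moves the clean mean trajectory by
  1–3 cents RMSE, i.e. on the order of the observation noise floor, so
  the accepted set must be confined to that neighbourhood for
  coordinate-wise medians to land on the parameter ridge.  At the 1%
  quantile of 2×10^4 sims the accepted threshold is far looser, medians
  shrink toward the prior center, and σ ordering between groups (a
  0.2-unit true difference) is lost in estimator bias — a budget
  limitation, not a property of the model.

## Synthetic observations

The empirical observations (behavioral group averages of 16 speakers with
cerebellar degeneration and 11 controls, 413 frames per 1.2 s trial) are
not publicly deposited.  The `synthetic` module generates stand-ins with
the same statistical structure: one simulator trial per pseudo-subject at
a known ground-truth θ, linearly interpolated to the 413-frame native
grid, plus per-subject smooth jitter (moving-average-smoothed white noise,
≈ 50 ms window, renormalized to unit SD) scaled so the across-subject
standard error of the mean sits at a configured level — 1.5 cents by
default, the midpoint of the empirically reported 0–3 cent range.  The
group mean and SE band ship with the ground truth in a JSON sidecar, so
recovery is testable end to end.  Native observations are downsampled to
the 300-frame simulator grid by linear interpolation (shape-preserving,
exact for constants and ramps, < 0.05 cents round-trip error for
band-limited responses).

Two ground-truth pairs are packaged: the **published pair** uses the
published inferred values for each group (Δa 91.5/102.7 ms, Δs
15.5/35.3 ms, log10 σ −5.6/−5.8, r 1.0/2.0, g_c 3.1/1.9 for CA/control) —
used for recovery and hypothesis evaluation; and an **rg-only pair** whose
members differ *only* in r and g_c — used to verify that the ablation
study attributes group differences to the right parameters.

What the generator does *not* emulate: subject-level physiology or
clinical heterogeneity, non-stationary baseline drift, and the exact
waveform of the empirical averages.  Passing tests therefore demonstrate
that the pipeline recovers parameters and attributes group differences
*under the model's own data-generating assumptions* plus realistic
noise — not that the published parameter values are correct for the real
cohorts.

## Experiments

- **Full fit**: repeated inference, pooling, summary; the inferred
  (median) set is validated by simulating 100 runs and reporting the mean
  trajectory, its per-frame SE (< 0.1 cents at the published sets) and the
  pointwise RMSE against the observation.
- **Ablation**: each parameter in turn is pinned to the control group's
  inferred value (a degenerate prior) and the remaining four are refit to
  the CA observation; refits of the control observation validate that the
  reduced models are not intrinsically handicapped.  Reduced-model
  posteriors carry exactly four free parameters.  Each reduced model is
  retrained from scratch (the restricted prior shapes its own training
  set).
- **Marginal sensitivity**: each parameter is set to median + k·SD for
  k ∈ {−2, −1, 0, 1, 2} (SD from the pooled posterior), others at their
  medians; each point is a fresh 100-run mean compared to an independent
  100-run baseline by RMSE.  Invalid values (delays below one frame)
  report "invalid"; fully diverging parameterizations report "unstable".

## Numerical choices and edge cases

- Nearest-integer delay rounding with a hard ≥ 1 frame validity floor.
- Diverging states are clipped at ±1e12 to keep arithmetic finite;
  clipping only affects runs already flagged unstable.
- ABC ties are broken by stable distance sort; all stochastic stages take
  explicit seeds and spawn independent substreams (`SeedSequence`), so
  identical (config, seed) reruns are bit-identical.
- The Gaussian-mixture backend excludes pinned (zero-variance) parameters
  from the density and re-inserts them at sampling; conditional
  covariances are symmetrized and given a 1e-12 jitter before Cholesky.
- The doubling iteration stops at a 1e-14 relative fixed-point change or
  60 iterations; a residual check (1e-10 relative) routes failures to the
  scipy solver.

## Known limitations

- Kalman gains are delay-free-optimal; delays are not integrated in the
  Riccati design (faithful to the source analysis, but suboptimal control
  theory by construction).
- Coordinate-wise posterior medians are not guaranteed to lie on the
  joint posterior ridge; at small inference budgets this is the dominant
  error in the reported "inferred value" (see Budgets above).
- The rejection-ABC posterior is conservative (tolerance-inflated); its
  credible intervals over-cover at desk budgets.
- Only the auditory channel is perturbed and only f_o is modelled;
  formant/articulatory control and adaptation paradigms are out of scope.
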