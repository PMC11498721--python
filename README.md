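# sfcpitch

State feedback control (SFC) modelling of voice pitch perturbation
responses, with simulation-based Bayesian inference of the model's control
parameters.

## The problem

When a speaker's auditory feedback is briefly pitch-shifted mid-utterance,
they compensate by shifting produced fundamental frequency (f_o) the other
way.  Speakers with cerebellar ataxia (CA) compensate roughly twice as
strongly as typical speakers — but a behavioral difference alone cannot say
*which* part of the speech motor system differs.  `sfcpitch` addresses this
by fitting a mechanistic control model to group-average perturbation
responses, so group differences become differences in interpretable
parameters.

The model is a state feedback control loop around an idealized larynx
(a damped spring-mass system, position read in cents of f_o, driven through
a command integrator and discretized by zero-order hold at 4 ms frames):
motor commands u = g_c·(x_target − x̂) are computed from an internal state
estimate x̂, maintained by efference-copy prediction plus correction from
delayed, noisy auditory and somatosensory feedback, weighted by the
steady-state Kalman gain K = P̂Cᵀ(CP̂Cᵀ + R)⁻¹ (P̂ from the discrete
algebraic Riccati equation).  Five parameters are tuned:

| parameter | meaning | prior |
|---|---|---|
| Δa | auditory feedback delay (ms) | U(50, 200) |
| Δs | somatosensory feedback delay (ms) | U(3, 80) |
| log₁₀ σ | overall feedback noise variance | U(−6.5, −3) |
| r | auditory : somatosensory noise variance ratio | U(0.1, 6) |
| g_c | controller gain | U(0.1, 8) |

Posteriors are recovered likelihood-free: simulate trials at prior draws,
then either keep the draws closest to the observation (rejection ABC, with
an optional local-linear regression correction) or condition a Gaussian-
mixture joint density on the observed trajectory.  Pooled posterior medians
are the "inferred values"; groups are compared with Glass's delta effect
sizes, parameter ablation (refitting with one parameter pinned to the other
group's value) and marginal sensitivity sweeps.

Because the original behavioral group averages are not publicly deposited,
the package ships a synthetic-data module that generates statistically
comparable group means (simulator trials per pseudo-subject plus smooth
jitter giving a 0–3 cent standard-error band, on the native 413-frame grid)
with known ground truth, so the whole pipeline is testable end to end.
See `docs/methods.md` for the full model and design notes.

## Worked example

```python
import sfcpitch as sp

# one simulated trial at the CA group's inferred parameter set
traj = sp.simulate_trial(sp.INFERRED_CA, seed=1)
print(traj.n_frames, traj.f_o.max().round(2))
# -> 300 36.56        (300 frames / 1.2 s; peak compensation ~37 cents)

# mean of 100 runs: the stochasticity of the loop is tiny
mean, se = sp.simulate_mean_response(sp.INFERRED_CA, n_runs=100, seed=1)
print(float(se.max()))
# -> 8.644e-05         (max per-frame SE of the mean, in cents)

# synthetic group observation with known ground truth, then inference
spec = sp.default_group_specs()["ca"]
resp = sp.generate_group_response(spec, seed=101)
obs = sp.downsample_to_simulator_grid(resp.trajectory)
cfg = sp.PipelineConfig(seed=7).desk_scale()   # 2e4 sims, 3 reps, ABC
fit = sp.full_fit(obs, cfg, label="ca")
print(fit.summary.table.round(2))
```

prints the per-parameter posterior summary, e.g.

```
             median  ci_low  ci_high     sd
delta_a_ms    79.94   51.43   140.69  24.63
delta_s_ms    33.48    4.26    74.36  21.41
sigma_log10   -5.09   -6.23    -4.18   0.52
r              1.28    0.72     1.74   0.27
g_c            4.05    2.19     7.63   1.48
```

— the ground truth (Δa 91.5, Δs 15.5, σ −5.6, r 1.0, g_c 3.1) falls inside
every 95% credible interval; the well-identified parameters (r, g_c)
concentrate, the delays stay broad, as expected from the loop's weak
sensitivity to them.

The same stages are available from the shell and compose:

```bash
sfcpitch synth --seed 5 --out-dir out
sfcpitch fit --observation out/ca_observation.csv --label ca \
             --backend abc --n-sims 20000 --n-reps 3 --seed 7 --out-dir out
sfcpitch ablate --obs-ca out/ca_observation.csv --obs-control out/control_observation.csv \
                --control-posterior out/control_posterior.csv --out-dir out
sfcpitch sensitivity --observation out/ca_observation.csv \
                     --posterior out/ca_posterior.csv --label ca --out-dir out
```

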