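"""State feedback control loop simulator for pitch perturbation trials.

Each frame of a trial runs: controller (target error × gain) → plant update
with process noise → sensory feedback with measurement noise → auditory
perturbation addend → observer (efference-copy prediction plus Kalman-weighted
correction from per-channel delayed prediction errors).  Produced pitch is the
noiseless auditory mapping of the plant state, in cents relative to baseline.

Two implementations are kept deliberately: a per-step reference loop built
from the named operations (`observer_step`, `control_law`, `apply_perturbation`)
and a vectorized batch loop (`simulate_batch`) that runs many trials at once.
Both consume the same pre-drawn noise streams and agree to floating-point
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .kalman import UnstableParameterizationError, batch_kalman_gains, compute_kalman_gain
from .params import SIGMA_Q, ParameterSet, noise_covariances
from .plant import DEFAULT_DT, DiscretePlant, default_discrete_plant

__all__ = [
    "PerturbationSpec",
    "Trajectory",
    "apply_perturbation",
    "control_law",
    "observer_step",
    "simulate_trial",
    "simulate_trial_reference",
    "simulate_batch",
    "simulate_mean_response",
    "INSTABILITY_THRESHOLD_CENTS",
    "DEFAULT_TRIAL_S",
]

#: |f_o| beyond this (cents) marks a run as unstable — far outside physiology
INSTABILITY_THRESHOLD_CENTS = 1e4

DEFAULT_TRIAL_S = 1.2


@dataclass(frozen=True)
class PerturbationSpec:
    """Auditory pitch perturbation: an addend on the auditory feedback channel.

    Defaults reproduce the −100 cent, 400 ms shift applied from trial onset;
    the somatosensory channel is never perturbed.
    """

    magnitude: float = -100.0
    onset: float = 0.0
    duration: float = 0.400

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration

    def to_dict(self) -> dict[str, float]:
        return {"magnitude": self.magnitude, "onset": self.onset, "duration": self.duration}


@dataclass
class Trajectory:
    """Produced pitch (cents vs. baseline) on a uniform frame grid."""

    t: np.ndarray
    f_o: np.ndarray
    pert: PerturbationSpec | None = None
    unstable: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_o = np.asarray(self.f_o, dtype=float)
        if self.t.shape != self.f_o.shape:
            raise ValueError("t and f_o must have identical length")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0


def apply_perturbation(y: np.ndarray, t: float, pert: PerturbationSpec) -> np.ndarray:
    """Add the perturbation to the auditory element of feedback y = (y_a, y_s)."""
    y = np.asarray(y, dtype=float).copy()
    if pert is not None and pert.active(t):
        y[0] += pert.magnitude
    return y


def control_law(x_target: np.ndarray, x_estimate: np.ndarray, g_c: float) -> float:
    """Motor command: controller gain times the position target error."""
    return float(g_c * (np.asarray(x_target)[0] - np.asarray(x_estimate)[0]))


def observer_step(
    prev_estimate: np.ndarray,
    u_prev: float,
    feedback_history: np.ndarray,
    prediction_history: np.ndarray,
    K: np.ndarray,
    delay_frames: tuple[int, int],
    plant: DiscretePlant,
    t_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One observer update at frame ``t_index``.

    Predicts the state from the efference copy of the previous command,
    writes the predicted feedback into ``prediction_history`` at the current
    frame, and corrects the prediction with per-channel prediction errors
    evaluated at each channel's own delay (zero before the trial start, since
    histories are zero-padded).

    Returns ``(x_estimate, x_predicted)``.
    """
    if min(delay_frames) < 1:
        raise ValueError("sensory delays must be at least one frame")
    x_predicted = plant.Ad @ prev_estimate + plant.Bd[:, 0] * u_prev
    prediction_history[t_index] = plant.Cd @ x_predicted
    y_error = np.zeros(2)
    for ch, d in enumerate(delay_frames):
        j = t_index - d
        if j >= 0:
            y_error[ch] = feedback_history[j, ch] - prediction_history[j, ch]
    x_estimate = x_predicted + K @ y_error
    return x_estimate, x_predicted


def _draw_noise(
    rng: np.random.Generator,
    n: int,
    n_frames: int,
    sigma_a: np.ndarray,
    sigma_s: np.ndarray,
    sigma_q: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-draw the loop's noise streams (shared by reference and batch paths).

    sigma_a / sigma_s are per-trial noise *variances*; returned arrays hold
    process noise w (n, n_frames, 3) and per-channel measurement noise.
    """
    w = rng.standard_normal((n, n_frames, 3)) * np.sqrt(sigma_q)
    va = rng.standard_normal((n, n_frames)) * np.sqrt(sigma_a)[:, None]
    vs = rng.standard_normal((n, n_frames)) * np.sqrt(sigma_s)[:, None]
    return w, va, vs


def simulate_trial_reference(
    params: ParameterSet,
    pert: PerturbationSpec | None = None,
    seed: int = 0,
    trial_s: float = DEFAULT_TRIAL_S,
    dt: float = DEFAULT_DT,
    sigma_q: float = SIGMA_Q,
) -> Trajectory:
    """Single trial via the explicit per-step loop (readable reference path)."""
    if pert is None:
        pert = PerturbationSpec()
    plant = default_discrete_plant(dt)
    n_frames = plant.n_frames(trial_s)
    delays = params.delay_frames(dt)
    gain = compute_kalman_gain(plant, noise_covariances(params))
    # same spawned stream as the first chunk of the batch path → exact agreement
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    w, va, vs = _draw_noise(
        rng, 1, n_frames, np.array([params.sigma_a]), np.array([params.sigma_s]), sigma_q
    )

    x = np.zeros(3)
    x_estimate = np.zeros(3)
    x_target = np.zeros(3)
    u_prev = 0.0
    feedback_history = np.zeros((n_frames, 2))
    prediction_history = np.zeros((n_frames, 2))
    f_o = np.zeros(n_frames)
    t_grid = np.arange(n_frames) * dt

    for t in range(n_frames):
        x = plant.Ad @ x + plant.Bd[:, 0] * u_prev + w[0, t]
        y = plant.Cd @ x + np.array([va[0, t], vs[0, t]])
        y = apply_perturbation(y, t_grid[t], pert)
        feedback_history[t] = y
        x_estimate, _ = observer_step(
            x_estimate, u_prev, feedback_history, prediction_history, gain.K, delays, plant, t
        )
        f_o[t] = (plant.Cd @ x)[0]
        u_prev = control_law(x_target, x_estimate, params.g_c)

    unstable = bool(np.any(~np.isfinite(f_o)) or np.max(np.abs(f_o)) > INSTABILITY_THRESHOLD_CENTS)
    return Trajectory(
        t=t_grid,
        f_o=f_o,
        pert=pert,
        unstable=unstable,
        meta={"params": params.to_dict(), "seed": int(seed)},
    )


_CLIP = 1e12  # keep diverging runs finite; only affects already-unstable trials


def simulate_batch(
    thetas: np.ndarray,
    pert: PerturbationSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    trial_s: float = DEFAULT_TRIAL_S,
    dt: float = DEFAULT_DT,
    sigma_q: float = SIGMA_Q,
    chunk_size: int = 4096,
    plant: DiscretePlant | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one trial per parameter row, vectorized across trials.

    The plant matrices are shared by all trials; per-trial quantities are the
    Kalman gain (from each θ's noise variances), the delay buffers, the
    controller gain and the noise scales.  Returns ``(f_o, unstable)`` with
    shapes (n, n_frames) and (n,).
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    if pert is None:
        pert = PerturbationSpec()
    if plant is None:
        plant = default_discrete_plant(dt)
    n_frames = plant.n_frames(trial_s)
    n = thetas.shape[0]
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    frame_ms = dt * 1000.0
    da = (thetas[:, 0] / frame_ms + 0.5).astype(np.int64)
    ds = (thetas[:, 1] / frame_ms + 0.5).astype(np.int64)
    if np.any(da < 1) or np.any(ds < 1):
        raise ValueError("sensory delays must round to at least one frame")
    sigma_a = 10.0 ** thetas[:, 2]
    sigma_s = sigma_a / thetas[:, 3]
    g_c = thetas[:, 4]
    K = batch_kalman_gains(plant, sigma_a, sigma_s, sigma_q)

    Ad_T = plant.Ad.T
    Bd = plant.Bd[:, 0]
    c_aud = plant.Cd[0]  # auditory output row (both channels sense the same quantity)
    c_som = plant.Cd[1]
    t_grid = np.arange(n_frames) * dt
    pert_on = np.array([pert.active(t) for t in t_grid])

    f = np.empty((n, n_frames))
    children = seed_seq.spawn(int(np.ceil(n / chunk_size)) or 1)
    for ci, start in enumerate(range(0, n, chunk_size)):
        sl = slice(start, min(start + chunk_size, n))
        m = sl.stop - sl.start
        rng = np.random.default_rng(children[ci])
        w, va, vs = _draw_noise(rng, m, n_frames, sigma_a[sl], sigma_s[sl], sigma_q)
        Kc = K[sl]
        Ka, Ks = Kc[:, :, 0], Kc[:, :, 1]
        dac, dsc, gcc = da[sl], ds[sl], g_c[sl]
        rows = np.arange(m)

        x = np.zeros((m, 3))
        xe = np.zeros((m, 3))
        u = np.zeros(m)
        ya_hist = np.zeros((m, n_frames))
        ys_hist = np.zeros((m, n_frames))
        ypa_hist = np.zeros((m, n_frames))

        with np.errstate(all="ignore"):
            for t in range(n_frames):
                x = x @ Ad_T + Bd[None, :] * u[:, None] + w[:, t]
                np.clip(x, -_CLIP, _CLIP, out=x)
                pos = x @ c_aud
                ya = pos + va[:, t]
                ys = x @ c_som + vs[:, t]
                if pert_on[t]:
                    ya = ya + pert.magnitude
                ya_hist[:, t] = ya
                ys_hist[:, t] = ys
                xp = xe @ Ad_T + Bd[None, :] * u[:, None]
                np.clip(xp, -_CLIP, _CLIP, out=xp)
                # both predicted channels equal the same predicted output
                ypa_hist[:, t] = xp @ c_aud
                ia = t - dac
                ma = ia >= 0
                ea = (ya_hist[rows, np.where(ma, ia, 0)] - ypa_hist[rows, np.where(ma, ia, 0)]) * ma
                isl = t - dsc
                ms_ = isl >= 0
                es = (ys_hist[rows, np.where(ms_, isl, 0)] - ypa_hist[rows, np.where(ms_, isl, 0)]) * ms_
                xe = xp + Ka * ea[:, None] + Ks * es[:, None]
                np.clip(xe, -_CLIP, _CLIP, out=xe)
                f[sl, t] = pos
                u = gcc * (0.0 - xe @ c_aud)

    with np.errstate(all="ignore"):
        unstable = ~np.isfinite(f).all(axis=1) | (
            np.nanmax(np.abs(f), axis=1) > INSTABILITY_THRESHOLD_CENTS
        )
    return f, unstable


def simulate_trial(
    params: ParameterSet,
    pert: PerturbationSpec | None = None,
    seed: int = 0,
    trial_s: float = DEFAULT_TRIAL_S,
    dt: float = DEFAULT_DT,
    sigma_q: float = SIGMA_Q,
    plant: DiscretePlant | None = None,
) -> Trajectory:
    """Simulate one perturbation trial; deterministic given the seed."""
    if pert is None:
        pert = PerturbationSpec()
    f, unstable = simulate_batch(
        params.to_array()[None, :], pert, seed=seed, trial_s=trial_s, dt=dt, sigma_q=sigma_q,
        plant=plant,
    )
    n_frames = f.shape[1]
    return Trajectory(
        t=np.arange(n_frames) * dt,
        f_o=f[0],
        pert=pert,
        unstable=bool(unstable[0]),
        meta={"params": params.to_dict(), "seed": int(seed)},
    )


def simulate_mean_response(
    params: ParameterSet,
    pert: PerturbationSpec | None = None,
    n_runs: int = 100,
    seed: int = 0,
    trial_s: float = DEFAULT_TRIAL_S,
    dt: float = DEFAULT_DT,
    sigma_q: float = SIGMA_Q,
    plant: DiscretePlant | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Per-frame mean and standard error over independent seeded trials.

    Unstable runs are excluded (and counted in the returned metadata); if all
    runs are unstable the parameterization is rejected outright.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2 to estimate a standard error")
    if pert is None:
        pert = PerturbationSpec()
    thetas = np.tile(params.to_array(), (n_runs, 1))
    f, unstable = simulate_batch(
        thetas, pert, seed=seed, trial_s=trial_s, dt=dt, sigma_q=sigma_q, plant=plant
    )
    ok = ~unstable
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise UnstableParameterizationError(
            f"all {n_runs} runs unstable at θ={params.to_dict()}"
        )
    mean = f[ok].mean(axis=0)
    se = f[ok].std(axis=0, ddof=1) / np.sqrt(n_ok)
    n_frames = f.shape[1]
    traj = Trajectory(
        t=np.arange(n_frames) * dt,
        f_o=mean,
        pert=pert,
        unstable=False,
        meta={
            "params": params.to_dict(),
            "seed": int(seed) if np.isscalar(seed) else None,
            "n_runs": n_runs,
            "n_unstable": n_runs - n_ok,
        },
    )
    return traj, se
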