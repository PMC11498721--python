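"""The three studies: full group fits, parameter ablation, marginal sensitivity.

``full_fit`` recovers the posterior over all five parameters for one observed
group-average response, reads off pooled medians as the inferred set, and
validates it by averaging simulator runs against the observation (RMSE).
``ablation_study`` refits four-parameter reduced models with each parameter in
turn pinned to the control group's inferred value, ranking parameters by how
much their ablation degrades the fit to the CA observation.
``marginal_sensitivity`` perturbs one parameter at a time by multiples of its
posterior SD and measures the departure of the mean output from baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .inference import (
    PosteriorSamples,
    PosteriorSummary,
    PriorSpec,
    fit_posterior,
    generate_training_set,
    pool_repetitions,
    rmse,
    summarize_posterior,
)
from .kalman import UnstableParameterizationError
from .params import PARAM_NAMES, ParameterSet, delay_ms_to_frames
from .simulate import Trajectory, simulate_mean_response

__all__ = [
    "FitResult",
    "AblationResult",
    "SensitivityResult",
    "full_fit",
    "ablation_study",
    "marginal_sensitivity",
]

log = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Posterior fit of one group plus its simulator validation."""

    label: str
    samples: PosteriorSamples
    summary: PosteriorSummary
    inferred: ParameterSet
    mean_trajectory: Trajectory
    mean_se: np.ndarray
    rmse_cents: float
    fixed: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "inferred": self.inferred.to_dict(),
            "fixed": self.fixed,
            "rmse_cents": self.rmse_cents,
            "max_se_cents": float(np.max(self.mean_se)),
            "summary": self.summary.table.to_dict(orient="index"),
        }


@dataclass
class AblationResult:
    """One reduced model: a single parameter pinned to the control value."""

    parameter: str
    fixed_value: float
    summary_reduced: PosteriorSummary  # 4-row table, ablated parameter absent
    rmse_ca: float
    rmse_control: float
    inferred_ca: ParameterSet
    inferred_control: ParameterSet

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "fixed_value": self.fixed_value,
            "rmse_ca": self.rmse_ca,
            "rmse_control": self.rmse_control,
            "inferred_ca": self.inferred_ca.to_dict(),
            "inferred_control": self.inferred_control.to_dict(),
            "summary_reduced": self.summary_reduced.table.to_dict(orient="index"),
        }


@dataclass
class SensitivityResult:
    """RMSE departure from baseline as one parameter sweeps ±k posterior SDs."""

    parameter: str
    offsets: list[float]
    values: list[float]  # parameter value at each offset
    rmse_from_baseline: list[float | str]  # number, or "invalid"/"unstable"

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "offsets": self.offsets,
            "values": self.values,
            "rmse_from_baseline": self.rmse_from_baseline,
        }


def _observation_on_grid(observation: Trajectory, config: PipelineConfig) -> Trajectory:
    n_frames = int(round(config.plant.trial_s / config.plant.dt))
    if observation.n_frames != n_frames:
        raise ValueError(
            f"observation has {observation.n_frames} frames; expected the simulator grid "
            f"of {n_frames} (downsample native observations first)"
        )
    return observation


def full_fit(
    observation: Trajectory,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    label: str = "",
    fixed: dict[str, float] | None = None,
    prior: PriorSpec | None = None,
) -> FitResult:
    """Run repeated inference on one observation, pool, summarize, validate.

    ``fixed`` pins parameters (degenerate prior) for reduced-model fits.
    Each repetition draws an independent training set (seed + repetition id)
    and fits a fresh backend; pooled medians define the inferred set, which is
    validated by RMSE between the n-run mean output and the observation.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    observation = _observation_on_grid(observation, config)
    prior = prior if prior is not None else config.prior.to_spec()
    if fixed:
        prior = prior.fix(**fixed)
    inf = config.inference
    pert = config.perturbation.to_spec()
    backend_kwargs: dict = {}
    if inf.backend == "abc":
        backend_kwargs["accept_quantile"] = inf.accept_quantile
        if inf.abc_adjust:
            backend_kwargs["adjust"] = "loclinear"
            backend_kwargs["n_features"] = inf.abc_adjust_features
            backend_kwargs["ridge"] = inf.abc_adjust_ridge
    else:
        backend_kwargs["n_components"] = inf.density_components
        backend_kwargs["n_features"] = inf.density_features

    reps = []
    for rep in range(inf.n_reps):
        rep_seed = int(seed) + rep
        log.info("fit %s: repetition %d/%d (seed %d)", label or "?", rep + 1, inf.n_reps, rep_seed)
        training = generate_training_set(
            prior,
            inf.n_sims,
            pert,
            training_noise_halfwidth=inf.training_noise_halfwidth,
            seed=rep_seed,
            trial_s=config.plant.trial_s,
            dt=config.plant.dt,
            sigma_q=config.plant.sigma_q,
        )
        if training.n_resampled_unstable:
            log.info("  resampled %d unstable training draws", training.n_resampled_unstable)
        reps.append(
            fit_posterior(
                training,
                observation,
                n_posterior_samples=inf.n_posterior_samples,
                seed=rep_seed,
                backend=inf.backend,
                prior=prior,
                repetition_id=rep,
                observation_id=label,
                **backend_kwargs,
            )
        )
    pooled = pool_repetitions(reps)
    summary = summarize_posterior(pooled)
    inferred = summary.inferred_parameter_set(fixed=fixed)
    mean_traj, se = simulate_mean_response(
        inferred,
        pert,
        n_runs=config.experiments.n_runs_mean,
        seed=int(seed) + 10_000,
        trial_s=config.plant.trial_s,
        dt=config.plant.dt,
        sigma_q=config.plant.sigma_q,
    )
    return FitResult(
        label=label,
        samples=pooled,
        summary=summary,
        inferred=inferred,
        mean_trajectory=mean_traj,
        mean_se=se,
        rmse_cents=rmse(mean_traj, observation),
        fixed=dict(fixed or {}),
    )


def _reduced_summary(summary: PosteriorSummary, ablated: str) -> PosteriorSummary:
    return PosteriorSummary(table=summary.table.drop(index=ablated))


def ablation_study(
    obs_ca: Trajectory,
    obs_control: Trajectory,
    control_fit: FitResult,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> list[AblationResult]:
    """Refit reduced 4-parameter models with each parameter pinned in turn.

    Each parameter is fixed to the control group's inferred value and the
    remaining four are refit to the CA observation (measuring how much of the
    group difference that parameter carries) and, as a method check, to the
    control observation (where RMSE should stay near the full-model fit).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    results = []
    for i, name in enumerate(PARAM_NAMES):
        fixed = {name: float(getattr(control_fit.inferred, name))}
        log.info("ablation: fixing %s = %g", name, fixed[name])
        fit_ca = full_fit(
            obs_ca, config, seed=int(seed) + 100 * (i + 1), label=f"ca[{name}]", fixed=fixed
        )
        fit_ctrl = full_fit(
            obs_control,
            config,
            seed=int(seed) + 100 * (i + 1) + 50,
            label=f"control[{name}]",
            fixed=fixed,
        )
        results.append(
            AblationResult(
                parameter=name,
                fixed_value=fixed[name],
                summary_reduced=_reduced_summary(fit_ca.summary, name),
                rmse_ca=fit_ca.rmse_cents,
                rmse_control=fit_ctrl.rmse_cents,
                inferred_ca=fit_ca.inferred,
                inferred_control=fit_ctrl.inferred,
            )
        )
    return results


def marginal_sensitivity(
    fit: FitResult,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    posterior_sds: dict[str, float] | None = None,
) -> list[SensitivityResult]:
    """Sweep each parameter ±k posterior SDs around the inferred set.

    Baseline is an independent n-run mean at the inferred set.  Parameter
    values that are invalid (a delay below one frame, or a non-positive
    ratio/gain) are marked "invalid"; parameterizations whose runs all
    diverge are marked "unstable", mirroring how such sweeps are reported.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    pert = config.perturbation.to_spec()
    n_runs = config.experiments.n_runs_mean
    sds = posterior_sds or {name: fit.summary.sd(name) for name in PARAM_NAMES}
    baseline, _ = simulate_mean_response(
        fit.inferred,
        pert,
        n_runs=n_runs,
        seed=int(seed) + 77_001,
        trial_s=config.plant.trial_s,
        dt=config.plant.dt,
        sigma_q=config.plant.sigma_q,
    )
    results = []
    for j, name in enumerate(PARAM_NAMES):
        offsets = list(config.experiments.sensitivity_offsets)
        values: list[float] = []
        errors: list[float | str] = []
        for oi, k in enumerate(offsets):
            value = float(getattr(fit.inferred, name) + k * sds[name])
            values.append(value)
            theta = fit.inferred.to_dict()
            theta[name] = value
            try:
                params = ParameterSet(**theta)
                delay_ms_to_frames(params.delta_a_ms, config.plant.dt)
                delay_ms_to_frames(params.delta_s_ms, config.plant.dt)
            except ValueError:
                errors.append("invalid")
                continue
            try:
                mean_traj, _ = simulate_mean_response(
                    params,
                    pert,
                    n_runs=n_runs,
                    seed=int(seed) + 80_000 + 100 * j + oi,
                    trial_s=config.plant.trial_s,
                    dt=config.plant.dt,
                    sigma_q=config.plant.sigma_q,
                )
            except UnstableParameterizationError:
                errors.append("unstable")
                continue
            errors.append(rmse(mean_traj, baseline))
        results.append(
            SensitivityResult(
                parameter=name, offsets=offsets, values=values, rmse_from_baseline=errors
            )
        )
    return results
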