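"""Simulation-based Bayesian inference of the five control-loop parameters.

Given an observed group-average perturbation response, draw parameters from a
uniform prior, simulate the loop for each draw (adding uniform training noise
to the outputs), and approximate the posterior p(θ | observation) with one of
two interchangeable backends:

``RejectionABC``
    classic rejection sampling: keep the quantile of training draws whose
    trajectory lies closest to the observation in pointwise RMSE.

``MixtureDensityPosterior``
    a conditional density estimator: a Gaussian mixture is fit jointly over
    (trajectory features, θ), then conditioned analytically on the observed
    trajectory's features and sampled.

Both are scikit-learn style estimators (``fit(X, y)`` on trajectories/θ pairs,
then ``sample``/``predict``) and both must satisfy the same parameter-recovery
properties.  Posteriors from repeated runs are pooled; summaries report the
median ("inferred value"), equal-tailed 95% credible interval and standard
deviation per parameter, and groups are compared with Glass's delta effect
sizes computed over bootstrap resamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .params import PARAM_NAMES, SIGMA_Q, ParameterSet
from .plant import DEFAULT_DT
from .simulate import DEFAULT_TRIAL_S, PerturbationSpec, Trajectory, simulate_batch

__all__ = [
    "PriorSpec",
    "TrainingSet",
    "PosteriorSamples",
    "PosteriorSummary",
    "EffectSizeReport",
    "sample_prior",
    "generate_training_set",
    "RejectionABC",
    "MixtureDensityPosterior",
    "fit_posterior",
    "pool_repetitions",
    "summarize_posterior",
    "glass_delta",
    "rmse",
    "evaluate_hypotheses",
]

# Table of default uniform prior bounds per parameter
_DEFAULT_BOUNDS = {
    "delta_a_ms": (50.0, 200.0),
    "delta_s_ms": (3.0, 80.0),
    "sigma_log10": (-6.5, -3.0),
    "r": (0.1, 6.0),
    "g_c": (0.1, 8.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors over θ.

    ``fixed`` pins parameters to a point value (degenerate bounds), which is
    how reduced models for the ablation study are expressed.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.bounds:
                raise ValueError(f"prior is missing bounds for {name!r}")
            lo, hi = self.bounds[name]
            if lo > hi:
                raise ValueError(f"prior for {name!r} has lower bound {lo} > upper bound {hi}")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def fix(self, **values: float) -> "PriorSpec":
        """Return a prior with the given parameters pinned to point values."""
        bounds = dict(self.bounds)
        for name, v in values.items():
            if name not in bounds:
                raise ValueError(f"unknown parameter {name!r}")
            bounds[name] = (float(v), float(v))
        return PriorSpec(bounds=bounds)

    @property
    def fixed_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if self.bounds[n][0] == self.bounds[n][1])

    def contains(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        return np.all((thetas >= self.lower) & (thetas <= self.upper), axis=1)


def sample_prior(
    prior: PriorSpec, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n i.i.d. uniform draws of θ within the prior bounds, shape (n, 5)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(prior.lower, prior.upper, size=(n, len(PARAM_NAMES)))


@dataclass
class TrainingSet:
    """Paired (θ, trajectory) draws used to train a posterior backend."""

    thetas: np.ndarray
    trajectories: np.ndarray
    pert: PerturbationSpec
    noise_halfwidth: float
    n_resampled_unstable: int = 0

    @property
    def n(self) -> int:
        return self.thetas.shape[0]


def generate_training_set(
    prior: PriorSpec,
    n_sims: int,
    pert: PerturbationSpec | None = None,
    training_noise_halfwidth: float = 3.5,
    seed: int = 0,
    trial_s: float = DEFAULT_TRIAL_S,
    dt: float = DEFAULT_DT,
    sigma_q: float = SIGMA_Q,
) -> TrainingSet:
    """Simulate a prior sample, resampling unstable draws, plus training noise.

    Each trajectory receives i.i.d. per-frame uniform noise on
    [−halfwidth, +halfwidth] cents, which regularizes the conditional density
    estimate against the near-determinism of the simulator.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    if pert is None:
        pert = PerturbationSpec()
    seq = np.random.SeedSequence([int(seed), 0x5F3C])
    theta_rng = np.random.default_rng(seq.spawn(1)[0])
    thetas = sample_prior(prior, n_sims, theta_rng)
    f, unstable = simulate_batch(thetas, pert, seed=seq.spawn(1)[0], trial_s=trial_s, dt=dt, sigma_q=sigma_q)
    n_resampled = 0
    for _ in range(100):
        if not unstable.any():
            break
        idx = np.nonzero(unstable)[0]
        n_resampled += idx.size
        thetas[idx] = sample_prior(prior, idx.size, theta_rng)
        f_new, un_new = simulate_batch(
            thetas[idx], pert, seed=seq.spawn(1)[0], trial_s=trial_s, dt=dt, sigma_q=sigma_q
        )
        f[idx] = f_new
        unstable[idx] = un_new
    else:
        raise RuntimeError("could not draw a stable training set from the prior")
    if training_noise_halfwidth > 0:
        noise_rng = np.random.default_rng(seq.spawn(1)[0])
        f = f + noise_rng.uniform(-training_noise_halfwidth, training_noise_halfwidth, size=f.shape)
    return TrainingSet(
        thetas=thetas,
        trajectories=f,
        pert=pert,
        noise_halfwidth=training_noise_halfwidth,
        n_resampled_unstable=n_resampled,
    )


@dataclass
class PosteriorSamples:
    """Draws over θ approximating p(θ | observation)."""

    samples: pd.DataFrame  # columns PARAM_NAMES + "repetition"
    observation_id: str = ""

    @property
    def n(self) -> int:
        return len(self.samples)

    def values(self) -> np.ndarray:
        return self.samples[list(PARAM_NAMES)].to_numpy()


@dataclass
class PosteriorSummary:
    """Per-parameter median, 95% equal-tailed credible interval and SD."""

    table: pd.DataFrame  # index: parameter; columns: median, ci_low, ci_high, sd

    def median(self, name: str) -> float:
        return float(self.table.loc[name, "median"])

    def sd(self, name: str) -> float:
        return float(self.table.loc[name, "sd"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])

    def inferred_parameter_set(self, fixed: dict[str, float] | None = None) -> ParameterSet:
        values = {}
        for name in PARAM_NAMES:
            if fixed and name in fixed:
                values[name] = float(fixed[name])
            else:
                values[name] = self.median(name)
        return ParameterSet(**values)


@dataclass
class EffectSizeReport:
    """Glass's delta (mean ± bootstrap SE) per parameter between two groups."""

    table: pd.DataFrame  # index: parameter; columns: delta_mean, delta_se

    def delta(self, name: str) -> float:
        return float(self.table.loc[name, "delta_mean"])


def _observation_vector(observation: Trajectory | np.ndarray, n_frames: int) -> np.ndarray:
    x = observation.f_o if isinstance(observation, Trajectory) else np.asarray(observation, float)
    if x.ndim != 1 or x.size != n_frames:
        raise ValueError(
            f"observation must be on the simulator grid ({n_frames} frames), got {x.shape}"
        )
    return x


class RejectionABC(BaseEstimator):
    """Rejection-ABC posterior: keep training θ closest to the observation.

    Distance is the pointwise trajectory RMSE (the same metric used to judge
    fit quality); the ``accept_quantile`` fraction of training draws with the
    smallest distances forms the accepted set, which is resampled with
    replacement to the requested posterior size.

    With ``adjust="loclinear"`` the accepted θ are post-processed with the
    classical local-linear regression correction: θ is regressed (ridge, with
    Epanechnikov distance weights) on whitened PCA features of the accepted
    trajectories and each draw is shifted to the observed feature point,
    removing most of the tolerance-induced shrinkage of the point estimates.
    Adjusted draws are clipped to the prior box when a prior is supplied.
    """

    def __init__(
        self,
        accept_quantile: float = 0.01,
        adjust: str | None = None,
        n_features: int = 10,
        ridge: float = 0.01,
        prior: PriorSpec | None = None,
    ):
        self.accept_quantile = accept_quantile
        self.adjust = adjust
        self.n_features = n_features
        self.ridge = ridge
        self.prior = prior

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RejectionABC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X (n, n_frames) and y (n, n_params) must be paired 2-D arrays")
        if X.shape[0] < 2:
            raise ValueError("training set too small for rejection sampling")
        self.X_ = X
        self.y_ = y
        if self.adjust == "loclinear":
            self.pca_ = PCA(n_components=min(self.n_features, X.shape[1]), whiten=True).fit(X)
        elif self.adjust is not None:
            raise ValueError(f"unknown adjustment {self.adjust!r}; use None or 'loclinear'")
        return self

    def _accepted(self, x_obs: np.ndarray) -> np.ndarray:
        dist = np.sqrt(np.mean((self.X_ - x_obs[None, :]) ** 2, axis=1))
        n_keep = max(1, int(math.ceil(self.accept_quantile * self.X_.shape[0])))
        idx = np.argpartition(dist, n_keep - 1)[:n_keep]
        # stable ordering for reproducibility
        idx = idx[np.argsort(dist[idx], kind="stable")]
        theta = self.y_[idx]
        if self.adjust == "loclinear" and n_keep > theta.shape[1] + 2:
            theta = self._loclinear(theta, self.X_[idx], dist[idx], x_obs)
        return theta

    def _loclinear(
        self, theta: np.ndarray, trajectories: np.ndarray, dist: np.ndarray, x_obs: np.ndarray
    ) -> np.ndarray:
        F = self.pca_.transform(trajectories) - self.pca_.transform(x_obs[None, :])
        t = dist / max(dist.max(), 1e-12)
        w = np.sqrt(1.0 - t**2 + 1e-6)[:, None]
        A = np.hstack([np.ones((F.shape[0], 1)), F])
        AtA = (A * w).T @ (A * w) + self.ridge * np.eye(A.shape[1])
        beta = np.linalg.solve(AtA, (A * w).T @ (theta * w))
        adjusted = theta - F @ beta[1:]
        if self.prior is not None:
            adjusted = np.clip(adjusted, self.prior.lower, self.prior.upper)
        return adjusted

    def sample(
        self,
        x_obs: np.ndarray,
        n_samples: int | None = None,
        random_state: int | np.random.Generator | None = 0,
    ) -> np.ndarray:
        accepted = self._accepted(_observation_vector(x_obs, self.X_.shape[1]))
        self.accepted_ = accepted
        if n_samples is None:
            return accepted.copy()
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        return accepted[rng.integers(0, accepted.shape[0], size=n_samples)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([np.median(self._accepted(row), axis=0) for row in X])


class MixtureDensityPosterior(BaseEstimator):
    """Conditional density estimator: joint Gaussian mixture over (features, θ).

    Trajectories are compressed with PCA (whitened) and θ is standardized;
    a full-covariance Gaussian mixture is fit to the joint vectors.  The
    posterior for an observation is the mixture conditioned on its features —
    an analytic Gaussian mixture over θ — truncated to the prior support by
    rejection.
    """

    def __init__(
        self,
        n_components: int = 8,
        n_features: int = 15,
        reg_covar: float = 1e-6,
        prior: PriorSpec | None = None,
        random_state: int | None = 0,
        max_iter: int = 200,
    ):
        self.n_components = n_components
        self.n_features = n_features
        self.reg_covar = reg_covar
        self.prior = prior
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MixtureDensityPosterior":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X (n, n_frames) and y (n, n_params) must be paired 2-D arrays")
        if X.shape[0] < 10 * self.n_components:
            raise ValueError(
                f"training set of {X.shape[0]} too small for {self.n_components} mixture components"
            )
        self.n_frames_ = X.shape[1]
        self.pca_ = PCA(n_components=min(self.n_features, X.shape[1]), whiten=True, random_state=self.random_state)
        F = self.pca_.fit_transform(X)
        # pinned (constant) parameters are excluded from the density and re-inserted at sampling
        self.y_mean_ = y.mean(axis=0)
        y_sd = y.std(axis=0)
        self.free_ = y_sd > 1e-12
        self.y_sd_ = np.where(self.free_, y_sd, 1.0)
        T = (y[:, self.free_] - self.y_mean_[self.free_]) / self.y_sd_[self.free_]
        Z = np.hstack([F, T])
        self.gmm_ = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            reg_covar=self.reg_covar,
            random_state=self.random_state,
            max_iter=self.max_iter,
        ).fit(Z)
        self.n_f_ = F.shape[1]
        return self

    def _conditional(self, f_obs: np.ndarray):
        """Condition the joint mixture on observed features; return (w, means, covs)."""
        d = self.n_f_
        w = np.empty(self.gmm_.n_components)
        means, covs = [], []
        for k in range(self.gmm_.n_components):
            mu = self.gmm_.means_[k]
            S = self.gmm_.covariances_[k]
            Sff, Sft = S[:d, :d], S[:d, d:]
            Stt = S[d:, d:]
            sol = np.linalg.solve(Sff, np.hstack([Sft, (f_obs - mu[:d])[:, None]]))
            gain, shift = sol[:, :-1], sol[:, -1]
            means.append(mu[d:] + Sft.T @ shift)
            cov = Stt - Sft.T @ gain
            covs.append((cov + cov.T) / 2.0)
            sign, logdet = np.linalg.slogdet(Sff)
            maha = (f_obs - mu[:d]) @ np.linalg.solve(Sff, f_obs - mu[:d])
            w[k] = np.log(self.gmm_.weights_[k]) - 0.5 * (logdet + maha)
        w = np.exp(w - w.max())
        w /= w.sum()
        return w, means, covs

    def sample(
        self,
        x_obs: np.ndarray,
        n_samples: int = 10_000,
        random_state: int | np.random.Generator | None = 0,
    ) -> np.ndarray:
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        f_obs = self.pca_.transform(
            _observation_vector(x_obs, self.n_frames_)[None, :]
        )[0]
        w, means, covs = self._conditional(f_obs)
        prior = self.prior if self.prior is not None else PriorSpec()
        lo = ((prior.lower - self.y_mean_) / self.y_sd_)[self.free_]
        hi = ((prior.upper - self.y_mean_) / self.y_sd_)[self.free_]
        chol = [np.linalg.cholesky(c + 1e-12 * np.eye(c.shape[0])) for c in covs]
        out = np.empty((0, int(self.free_.sum())))
        for _ in range(200):  # rejection against the prior box
            need = n_samples - out.shape[0]
            if need <= 0:
                break
            comp = rng.choice(len(w), size=need, p=w)
            draws = np.empty((need, out.shape[1]))
            for k in np.unique(comp):
                mask = comp == k
                z = rng.standard_normal((int(mask.sum()), out.shape[1]))
                draws[mask] = means[k][None, :] + z @ chol[k].T
            ok = np.all((draws >= lo) & (draws <= hi), axis=1)
            out = np.vstack([out, draws[ok]])
        if out.shape[0] < n_samples:
            # pathological posterior mass outside the box: clip the remainder
            need = n_samples - out.shape[0]
            comp = rng.choice(len(w), size=need, p=w)
            extra = np.vstack([means[k] for k in comp])
            out = np.vstack([out, np.clip(extra, lo, hi)])
        out = out[:n_samples]
        theta = np.tile(self.y_mean_, (n_samples, 1))
        theta[:, self.free_] = out * self.y_sd_[self.free_] + self.y_mean_[self.free_]
        return theta

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack(
            [np.median(self.sample(row, 2000, random_state=0), axis=0) for row in X]
        )


_BACKENDS = {"abc": RejectionABC, "density": MixtureDensityPosterior}


def fit_posterior(
    training: TrainingSet,
    observation: Trajectory | np.ndarray,
    n_posterior_samples: int = 10_000,
    seed: int = 0,
    backend: str = "abc",
    prior: PriorSpec | None = None,
    repetition_id: int = 0,
    observation_id: str = "",
    **backend_kwargs,
) -> PosteriorSamples:
    """Fit one posterior repetition with the chosen backend and sample it."""
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {sorted(_BACKENDS)}")
    x_obs = _observation_vector(observation, training.trajectories.shape[1])
    backend_kwargs.setdefault("prior", prior)
    if backend == "density":
        backend_kwargs.setdefault("random_state", seed)
    est = _BACKENDS[backend](**backend_kwargs)
    est.fit(training.trajectories, training.thetas)
    draws = est.sample(x_obs, n_samples=n_posterior_samples, random_state=seed)
    df = pd.DataFrame(draws, columns=list(PARAM_NAMES))
    df["repetition"] = repetition_id
    return PosteriorSamples(samples=df, observation_id=observation_id)


def pool_repetitions(reps: list[PosteriorSamples]) -> PosteriorSamples:
    """Concatenate repetitions of inference over the same observation."""
    if not reps:
        raise ValueError("need at least one repetition to pool")
    obs_ids = {r.observation_id for r in reps}
    if len(obs_ids) > 1:
        raise ValueError(f"cannot pool repetitions over different observations: {obs_ids}")
    return PosteriorSamples(
        samples=pd.concat([r.samples for r in reps], ignore_index=True),
        observation_id=reps[0].observation_id,
    )


def summarize_posterior(samples: PosteriorSamples) -> PosteriorSummary:
    """Median, equal-tailed 95% CI and SD for each parameter."""
    if samples.n < 100:
        raise ValueError(f"need at least 100 posterior samples, got {samples.n}")
    rows = {}
    for name in PARAM_NAMES:
        v = samples.samples[name].to_numpy()
        rows[name] = {
            "median": float(np.median(v)),
            "ci_low": float(np.quantile(v, 0.025)),
            "ci_high": float(np.quantile(v, 0.975)),
            "sd": float(np.std(v, ddof=1)),
        }
    return PosteriorSummary(table=pd.DataFrame(rows).T.loc[list(PARAM_NAMES)])


def glass_delta(
    samples_A: PosteriorSamples | np.ndarray,
    samples_B: PosteriorSamples | np.ndarray,
    n_boot: int = 100,
    boot_size: int = 1000,
    seed: int = 0,
) -> EffectSizeReport:
    """Glass's delta (mean_A − mean_B over SD_B) per parameter, bootstrapped.

    Each bootstrap resample draws ``boot_size`` values with replacement from
    both groups and computes delta; the report carries the mean and standard
    error over the ``n_boot`` resamples.
    """
    A = samples_A.values() if isinstance(samples_A, PosteriorSamples) else np.atleast_2d(samples_A)
    B = samples_B.values() if isinstance(samples_B, PosteriorSamples) else np.atleast_2d(samples_B)
    if A.size == 0 or B.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if np.any(B.std(axis=0, ddof=1) <= 0):
        raise ValueError("comparison group has zero standard deviation")
    rng = np.random.default_rng(seed)
    deltas = np.empty((n_boot, A.shape[1]))
    for b in range(n_boot):
        a = A[rng.integers(0, A.shape[0], boot_size)]
        bb = B[rng.integers(0, B.shape[0], boot_size)]
        deltas[b] = (a.mean(axis=0) - bb.mean(axis=0)) / bb.std(axis=0, ddof=1)
    table = pd.DataFrame(
        {"delta_mean": deltas.mean(axis=0), "delta_se": deltas.std(axis=0, ddof=1)},
        index=list(PARAM_NAMES)[: A.shape[1]],
    )
    return EffectSizeReport(table=table)


def rmse(a: np.ndarray | Trajectory, b: np.ndarray | Trajectory) -> float:
    """Pointwise root mean square error between two equal-length trajectories."""
    x = a.f_o if isinstance(a, Trajectory) else np.asarray(a, dtype=float)
    y = b.f_o if isinstance(b, Trajectory) else np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def evaluate_hypotheses(
    summary_CA: PosteriorSummary,
    summary_control: PosteriorSummary,
    effects: EffectSizeReport | None = None,
) -> dict:
    """Evaluate the two group-difference hypotheses on pooled medians.

    H1 (greater relative reliance on auditory feedback in CA): r_CA < r_control.
    H2 (greater reliance on all feedback in CA): σ_CA < σ_control.
    """
    report = {
        "H1_r_ca_lt_control": bool(summary_CA.median("r") < summary_control.median("r")),
        "H2_sigma_ca_lt_control": bool(
            summary_CA.median("sigma_log10") < summary_control.median("sigma_log10")
        ),
        "medians_CA": {n: summary_CA.median(n) for n in PARAM_NAMES},
        "medians_control": {n: summary_control.median(n) for n in PARAM_NAMES},
    }
    if effects is not None:
        report["glass_delta"] = {
            n: float(effects.table.loc[n, "delta_mean"]) for n in effects.table.index
        }
    return report
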