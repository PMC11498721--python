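"""Tunable control/observer parameters and their noise-covariance mapping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import DEFAULT_DT

__all__ = [
    "PARAM_NAMES",
    "SIGMA_Q",
    "ParameterSet",
    "NoiseSpec",
    "noise_covariances",
    "delay_ms_to_frames",
]

#: canonical ordering of the five tunable parameters θ
PARAM_NAMES = ("delta_a_ms", "delta_s_ms", "sigma_log10", "r", "g_c")

#: process-noise variance on each state element, held constant
SIGMA_Q = 1e-8


def delay_ms_to_frames(delay_ms: float, dt: float = DEFAULT_DT) -> int:
    """Convert a sensory delay in ms to whole frames (nearest-integer rounding).

    A delay is physically meaningful only if it spans at least one frame of the
    simulation; values rounding to zero frames raise.
    """
    frames = int(delay_ms / (dt * 1000.0) + 0.5)
    if frames < 1:
        raise ValueError(
            f"delay of {delay_ms} ms is below one frame ({dt * 1000:.0f} ms grid); "
            "invalid parameter value"
        )
    return frames


@dataclass(frozen=True)
class ParameterSet:
    """The five tunable parameters θ = {Δa, Δs, σ, r, gc}.

    delta_a_ms, delta_s_ms : auditory / somatosensory feedback delays (ms)
    sigma_log10 : overall feedback noise variance exponent; σ = 10**sigma_log10
    r : ratio of auditory to somatosensory noise variance (σa = σ, σs = σ/r)
    g_c : controller gain on the target error
    """

    delta_a_ms: float
    delta_s_ms: float
    sigma_log10: float
    r: float
    g_c: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r) or self.r <= 0:
            raise ValueError(f"noise ratio r must be strictly positive, got {self.r}")
        if not np.isfinite(self.g_c) or self.g_c <= 0:
            raise ValueError(f"controller gain g_c must be strictly positive, got {self.g_c}")

    @property
    def sigma_a(self) -> float:
        return 10.0 ** self.sigma_log10

    @property
    def sigma_s(self) -> float:
        return self.sigma_a / self.r

    def delay_frames(self, dt: float = DEFAULT_DT) -> tuple[int, int]:
        return delay_ms_to_frames(self.delta_a_ms, dt), delay_ms_to_frames(self.delta_s_ms, dt)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected θ of shape ({len(PARAM_NAMES)},), got {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}


@dataclass(frozen=True)
class NoiseSpec:
    """Process and measurement noise covariances of the control loop.

    Q is isotropic process noise on the plant state (σq per element, fixed);
    R = diag(σa, σs) is measurement noise on the (auditory, somatosensory)
    feedback channels.
    """

    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        for name, M in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(M, M.T) or np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError(f"{name} must be symmetric positive definite")


def noise_covariances(params: ParameterSet, n_states: int = 3, sigma_q: float = SIGMA_Q) -> NoiseSpec:
    """Map θ's noise parameters onto the loop covariances.

    R = diag(10**sigma_log10, 10**sigma_log10 / r); Q = σq·I on the plant state.
    """
    if params.r <= 0:
        raise ValueError(f"noise ratio r must be strictly positive, got {params.r}")
    Q = sigma_q * np.eye(n_states)
    R = np.diag([params.sigma_a, params.sigma_s])
    return NoiseSpec(Q=Q, R=R)
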