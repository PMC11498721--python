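"""Steady-state Kalman gain of the observer via the discrete algebraic Riccati equation.

The observer corrects its state prediction with sensory prediction errors
weighted by the steady-state Kalman gain K = P̂Cᵀ(CP̂Cᵀ + R)⁻¹, where P̂ solves
the (estimation-form) DARE

    A P Aᵀ − P − A P Cᵀ (C P Cᵀ + R)⁻¹ C P Aᵀ + Q = 0.

Sensory delays live outside the state equations (history buffers in the
simulator), so the gain is optimal with respect to the delay-free model.

Two routes are provided: a per-system scipy solve (reference) and a batched
structure-preserving doubling iteration used when evaluating many noise
parameterizations at once (the prior sweep of simulation-based inference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .params import SIGMA_Q, NoiseSpec
from .plant import DiscretePlant

__all__ = [
    "KalmanGain",
    "UnstableParameterizationError",
    "compute_kalman_gain",
    "batch_kalman_gains",
    "dare_residual",
]


class UnstableParameterizationError(RuntimeError):
    """Raised when a parameterization admits no valid steady-state solution."""


@dataclass(frozen=True)
class KalmanGain:
    """Steady-state Riccati solution and the resulting gain matrix.

    ``K`` has one column per feedback channel: ``K_a`` weights auditory
    prediction errors, ``K_s`` somatosensory ones.
    """

    P_hat: np.ndarray
    K: np.ndarray

    @property
    def K_a(self) -> np.ndarray:
        return self.K[:, 0]

    @property
    def K_s(self) -> np.ndarray:
        return self.K[:, 1]


def dare_residual(P: np.ndarray, plant: DiscretePlant, noise: NoiseSpec) -> float:
    """Max-abs residual of the estimation DARE at P."""
    A, C = plant.Ad, plant.Cd
    S = C @ P @ C.T + noise.R
    res = A @ P @ A.T - P - A @ P @ C.T @ np.linalg.solve(S, C @ P @ A.T) + noise.Q
    return float(np.max(np.abs(res)))


def compute_kalman_gain(plant: DiscretePlant, noise: NoiseSpec) -> KalmanGain:
    """Solve the DARE for the plant/noise pair and form the steady-state gain."""
    A, C = plant.Ad, plant.Cd
    try:
        P = scipy.linalg.solve_discrete_are(A.T, C.T, noise.Q, noise.R)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError) as exc:
        raise UnstableParameterizationError(
            f"Riccati solve failed for R=diag{tuple(np.diag(noise.R))}: {exc}"
        ) from exc
    if not np.all(np.isfinite(P)):
        raise UnstableParameterizationError("Riccati solution is not finite")
    S = C @ P @ C.T + noise.R
    K = P @ C.T @ np.linalg.inv(S)
    if not np.all(np.isfinite(K)):
        raise UnstableParameterizationError("Kalman gain is not finite")
    return KalmanGain(P_hat=P, K=K)


def batch_kalman_gains(
    plant: DiscretePlant,
    sigma_a: np.ndarray,
    sigma_s: np.ndarray,
    sigma_q: float = SIGMA_Q,
    n_iter: int = 60,
) -> np.ndarray:
    """Steady-state gains for many measurement-noise pairs at once.

    Runs the structure-preserving doubling iteration for the estimation DARE
    (quadratically convergent) on a batch of diagonal R = diag(σa, σs), all
    sharing the plant and Q = σq·I.  Entries whose residual exceeds tolerance
    are recomputed with the scipy reference solver.

    Returns an array of shape (n, n_states, 2).
    """
    sigma_a = np.asarray(sigma_a, dtype=float)
    sigma_s = np.asarray(sigma_s, dtype=float)
    n = sigma_a.shape[0]
    ns = plant.n_states
    A, C = plant.Ad, plant.Cd
    Q = sigma_q * np.eye(ns)
    eye = np.eye(ns)

    # estimation DARE == control DARE for (Aᵀ, Cᵀ): iterate with A0=Aᵀ, G0=CᵀR⁻¹C, H0=Q
    A_k = np.broadcast_to(A.T, (n, ns, ns)).copy()
    G_k = np.einsum("ji,nj,jk->nik", C, 1.0 / np.stack([sigma_a, sigma_s], axis=1), C)
    H_k = np.broadcast_to(Q, (n, ns, ns)).copy()

    with np.errstate(all="ignore"):
        for _ in range(n_iter):
            W = np.linalg.inv(eye + G_k @ H_k)
            AW = A_k @ W
            A_next = AW @ A_k
            G_next = G_k + AW @ G_k @ np.transpose(A_k, (0, 2, 1))
            H_next = H_k + np.transpose(A_k, (0, 2, 1)) @ H_k @ W @ A_k
            if np.all(np.isfinite(H_next)):
                delta = np.max(np.abs(H_next - H_k))
                scale = max(1.0, float(np.max(np.abs(H_next))))
                A_k, G_k, H_k = A_next, G_next, H_next
                if delta < 1e-14 * scale:
                    break
            else:
                A_k, G_k, H_k = A_next, G_next, H_next
                break

    P = H_k
    # gain K = P Cᵀ (C P Cᵀ + R)⁻¹, batched over the diagonal R
    PCt = P @ C.T
    S = np.einsum("ij,njk->nik", C, PCt)
    S[:, 0, 0] += sigma_a
    S[:, 1, 1] += sigma_s
    with np.errstate(all="ignore"):
        K = PCt @ np.linalg.inv(S)

    # verify, falling back to the reference solver where doubling drifted
    bad = ~np.all(np.isfinite(K), axis=(1, 2))
    for i in range(n):
        if not bad[i]:
            Pi = P[i]
            Si = C @ Pi @ C.T + np.diag([sigma_a[i], sigma_s[i]])
            res = A @ Pi @ A.T - Pi - A @ Pi @ C.T @ np.linalg.solve(Si, C @ Pi @ A.T) + Q
            tol = 1e-10 * max(1.0, float(np.max(np.abs(Pi))))
            if np.max(np.abs(res)) > tol:
                bad[i] = True
    for i in np.nonzero(bad)[0]:
        noise = NoiseSpec(Q=Q, R=np.diag([sigma_a[i], sigma_s[i]]))
        K[i] = compute_kalman_gain(plant, noise).K
    return K
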