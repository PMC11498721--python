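"""Laryngeal plant: spring-mass pitch dynamics with an upstream command integrator.

The larynx is idealized as a damped spring-mass system whose spring rest length
is linearly related to produced fundamental frequency (f_o), so the position
state is read directly in cents of f_o deviation from baseline.  Motor commands
are rate commands: an integrator (continuous-time A=0, B=1, C=1) sits on the
control path upstream of the spring-mass system, accumulating controller output
into the plant input.  The full series system is discretized exactly with a
zero-order hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import cont2discrete

__all__ = [
    "PlantConstants",
    "ContinuousPlant",
    "DiscretePlant",
    "build_plant",
    "discretize_and_cascade",
    "default_discrete_plant",
    "DEFAULT_DT",
]

#: default sampling time (s); 1.2 s trials give 300 frames
DEFAULT_DT = 0.004


@dataclass(frozen=True)
class PlantConstants:
    """Anatomical constants of the spring-mass larynx.

    Defaults give the stiffness-to-mass ratio k/m = 160000 and damping-to-mass
    ratio b/m = 1600 used throughout; the constants are held fixed, only the
    control/observer parameters are tuned.
    """

    k: float = 160000.0
    b: float = 1600.0
    m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k", "b", "m"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"plant constant {name!r} must be strictly positive, got {value}")


@dataclass(frozen=True)
class ContinuousPlant:
    """Continuous-time spring-mass state space (state = [position, velocity]).

    C maps the position identically onto both feedback channels
    (auditory and somatosensory both sense produced pitch/laryngeal position).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray


@dataclass(frozen=True)
class DiscretePlant:
    """Zero-order-hold discretization of integrator + spring-mass in series.

    State is [position, velocity, integrated command]; ``Cd`` maps position to
    the two sensory channels.  ``n_frames`` converts a trial duration to the
    frame count of the uniform grid.
    """

    Ad: np.ndarray
    Bd: np.ndarray
    Cd: np.ndarray
    dt: float = DEFAULT_DT

    def n_frames(self, trial_s: float) -> int:
        return int(round(trial_s / self.dt))

    @property
    def n_states(self) -> int:
        return self.Ad.shape[0]


def build_plant(constants: PlantConstants | None = None) -> ContinuousPlant:
    """Build the continuous spring-mass larynx model from its constants."""
    if constants is None:
        constants = PlantConstants()
    km = constants.k / constants.m
    bm = constants.b / constants.m
    A = np.array([[0.0, 1.0], [-km, -bm]])
    B = np.array([[0.0], [km]])
    C = np.array([[1.0, 0.0], [1.0, 0.0]])
    return ContinuousPlant(A=A, B=B, C=C)


def discretize_and_cascade(
    plant: ContinuousPlant, dt: float = DEFAULT_DT, integrator_upstream: bool = True
) -> DiscretePlant:
    """Cascade the command integrator with the plant and ZOH-discretize.

    With ``integrator_upstream`` (the default), the integrator (A=0, B=1, C=1)
    precedes the spring-mass system: controller output is a rate command whose
    integral drives the plant input, and the plant position is the
    pitch-determining state.  The alternative ordering (integrator downstream,
    accumulating the plant position into the sensed output) is kept for
    comparison.  Either way the series connection is discretized as one
    combined 3-state model so the hold is exact for the true cascade.
    """
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"sampling time dt must be strictly positive, got {dt}")
    A2, B2 = plant.A, plant.B
    A_full = np.zeros((3, 3))
    C_full = np.zeros((2, 3))
    if integrator_upstream:
        # state [position, velocity, z] with z' = u, plant input = z
        A_full[:2, :2] = A2
        A_full[:2, 2:] = B2
        B_full = np.array([[0.0], [0.0], [1.0]])
        C_full[:, :2] = plant.C
    else:
        # state [position, velocity, z] with z' = position, output = z
        A_full[:2, :2] = A2
        A_full[2, 0] = 1.0
        B_full = np.zeros((3, 1))
        B_full[:2] = B2
        C_full[:, 2] = 1.0
    Ad, Bd, Cd, _, _ = cont2discrete((A_full, B_full, C_full, np.zeros((2, 1))), dt, method="zoh")
    return DiscretePlant(Ad=Ad, Bd=Bd, Cd=Cd, dt=dt)


_default_cache: dict[float, DiscretePlant] = {}


def default_discrete_plant(dt: float = DEFAULT_DT) -> DiscretePlant:
    """Default discretized cascade (fixed anatomical constants), cached per dt."""
    if dt not in _default_cache:
        _default_cache[dt] = discretize_and_cascade(build_plant(), dt)
    return _default_cache[dt]
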