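"""Shared fixtures: plants, parameter sets, synthetic observations, desk-scale fits.

Expensive inference runs (used by several acceptance checks) are session-scoped
so they are computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import sfcpitch as sp
from sfcpitch.config import PipelineConfig


@pytest.fixture(scope="session")
def plant():
    return sp.plant.default_discrete_plant()


@pytest.fixture(scope="session")
def ca_params():
    return sp.INFERRED_CA


@pytest.fixture(scope="session")
def control_params():
    return sp.INFERRED_CONTROL


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    """Reduced-budget configuration: ABC backend, 2e4 sims, 3 repetitions."""
    return PipelineConfig(seed=7).desk_scale()


@pytest.fixture(scope="session")
def published_observations(desk_config):
    """Synthetic CA/control observations with the inferred group values as truth."""
    out = {}
    for key, spec in sp.default_group_specs().items():
        resp = sp.generate_group_response(spec, seed=101 if key == "ca" else 102)
        obs = sp.downsample_to_simulator_grid(resp.trajectory)
        out[key] = (obs, spec.ground_truth)
    return out


@pytest.fixture(scope="session")
def headline_config() -> PipelineConfig:
    """Budget for the group-comparison/ablation studies: 6e4 sims, 3 reps,
    tight-quantile regression-adjusted ABC."""
    return PipelineConfig(seed=7).headline_scale()


@pytest.fixture(scope="session")
def published_fits_desk(desk_config, published_observations):
    """Desk-scale (plain-ABC) full fits of the packaged pair, for recovery checks."""
    fits = {}
    for key, (obs, _) in published_observations.items():
        fits[key] = sp.full_fit(obs, desk_config, seed=desk_config.seed, label=key)
    return fits


@pytest.fixture(scope="session")
def published_fits(headline_config, published_observations):
    """Headline-scale fits of the packaged pair, for the group comparison."""
    fits = {}
    for key, (obs, _) in published_observations.items():
        fits[key] = sp.full_fit(obs, headline_config, seed=headline_config.seed, label=key)
    return fits


@pytest.fixture(scope="session")
def rg_observations():
    """Synthetic pair whose ground truths differ only in r and g_c."""
    out = {}
    for key, spec in sp.rg_only_group_specs().items():
        resp = sp.generate_group_response(spec, seed=201 if key == "ca" else 202)
        obs = sp.downsample_to_simulator_grid(resp.trajectory)
        out[key] = (obs, spec.ground_truth)
    return out


@pytest.fixture(scope="session")
def rg_ablation(headline_config, rg_observations):
    """Control full fit + five-parameter ablation on the r/g_c-only pair."""
    obs_ca, _ = rg_observations["ca"]
    obs_ctrl, _ = rg_observations["control"]
    cfg = headline_config
    control_fit = sp.full_fit(obs_ctrl, cfg, seed=cfg.seed + 1, label="control")
    results = sp.ablation_study(obs_ca, obs_ctrl, control_fit, cfg, seed=cfg.seed)
    return control_fit, results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
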