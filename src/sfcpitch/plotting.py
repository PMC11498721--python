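"""Minimal figures: model fit overlay and posterior marginals."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .params import PARAM_NAMES
from .simulate import Trajectory


def plot_fit(observation: Trajectory, fit_result) -> plt.Figure:
    """Observed group mean vs. fitted 100-run simulator mean."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(observation.t, observation.f_o, ":", color="0.3", label="observation")
    m = fit_result.mean_trajectory
    ax.plot(m.t, m.f_o, "-", color="C0",
            label=f"model (RMSE {fit_result.rmse_cents:.2f} cents)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("produced pitch (cents)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_posterior(samples, truth: dict | None = None) -> plt.Figure:
    """Histogram of each pooled posterior marginal."""
    fig, axes = plt.subplots(1, len(PARAM_NAMES), figsize=(3 * len(PARAM_NAMES), 3))
    for ax, name in zip(axes, PARAM_NAMES):
        ax.hist(samples.samples[name], bins=40, color="C0", alpha=0.8)
        if truth and name in truth:
            ax.axvline(truth[name], color="k", ls="--")
        ax.set_title(name)
    fig.tight_layout()
    return fig
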