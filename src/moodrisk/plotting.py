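"""Quick-look plots for fitted models and cluster statistics."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_mood_fit", "plot_choice_curves", "plot_cluster_t"]


def plot_mood_fit(results, rated_trials=None, ratings_z=None, ax=None):
    """Fitted TML trajectory with the observed (z-scored) ratings overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    tml = results.fitted_tml.tml
    ax.plot(np.arange(1, tml.size + 1), tml, label="TML", color="C0")
    if rated_trials is not None and ratings_z is not None:
        ax.scatter(rated_trials, ratings_z, color="C3", s=18, zorder=3, label="ratings (z)")
    ax.set_xlabel("trial")
    ax.set_ylabel("mood (z)")
    ax.legend(frameon=False)
    return ax


def plot_choice_curves(results, gains, losses, ax=None, bins=8):
    """Observed acceptance rate vs. modelled probability along the gain axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    order = np.argsort(gains)
    g = np.asarray(gains)[order]
    p = results.p_accept[order]
    c = (results.p_accept + results.residuals)[order]
    edges = np.linspace(g.min(), g.max(), bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(g, edges) - 1, 0, bins - 1)
    obs = [c[which == b].mean() if np.any(which == b) else np.nan for b in range(bins)]
    mod = [p[which == b].mean() if np.any(which == b) else np.nan for b in range(bins)]
    ax.plot(centers, obs, "o", color="k", label="observed")
    ax.plot(centers, mod, "--", color="C1", label="model")
    ax.set_xlabel("gain (euros)")
    ax.set_ylabel("p(accept)")
    ax.legend(frameon=False)
    return ax


def plot_cluster_t(result, ax=None):
    """Across-site t series with significant clusters highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    times = result.times if result.times is not None else np.arange(result.t_obs.size)
    ax.plot(times, result.t_obs, color="C0")
    ax.axhline(0, color="k", lw=0.5)
    for c in result.clusters:
        if c["p_corr"] < 0.05:
            ax.axvspan(c["start_s"], c["end_s"], color="C1", alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("t across sites")
    return ax
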