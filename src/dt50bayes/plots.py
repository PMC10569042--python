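"""Optional plotting hooks: cohort histograms and per-substance panels."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .censoring import Censoring, Observation
from .inference import PosteriorDraws


def plot_cohort_histograms(results: pd.DataFrame, axes=None):
    """Overlaid histograms of descriptive vs inferred means and sds."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_mu, ax_sd = axes
    bins = np.linspace(-2, 4, 40)
    ax_mu.hist(results["desc_mean"].dropna(), bins=bins, alpha=0.6,
               color="tab:orange", label="descriptive mean")
    ax_mu.hist(results["mu_mean"], bins=bins, alpha=0.6,
               color="tab:blue", label="inferred mean")
    ax_mu.set_xlabel("mean log10 DT50 [log(d)]")
    ax_mu.legend()
    bins_sd = np.linspace(0, 2, 40)
    ax_sd.hist(results["desc_std"].dropna(), bins=bins_sd, alpha=0.6,
               color="tab:orange", label="descriptive sd")
    ax_sd.hist(results["sigma_mean"], bins=bins_sd, alpha=0.6,
               color="tab:blue", label="inferred sd")
    ax_sd.set_xlabel("sd of log10 DT50 [log(d)]")
    ax_sd.legend()
    return axes


def plot_substance_panel(
    observations: list[Observation],
    draws: PosteriorDraws,
    sigma_min: float = 0.2,
    n_curves: int = 200,
    rng: np.random.Generator | None = None,
    ax=None,
):
    """One per-substance panel: data points, censoring bounds, and a spread
    of posterior normal densities (a random subset of draws)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    rng = rng or np.random.default_rng(0)
    grid = np.linspace(-3, 5, 400)
    idx = rng.choice(len(draws), size=min(n_curves, len(draws)), replace=False)
    for k in idx:
        s = draws.sigma[k] + sigma_min
        dens = np.exp(-0.5 * ((grid - draws.mu[k]) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        ax.plot(grid, dens, color="tab:blue", alpha=0.03, lw=0.8)
    values = [o.value_log10 for o in observations if o.censoring is Censoring.NONE]
    ax.plot(values, np.full(len(values), -0.02), "k|", ms=10, label="reported")
    for o in observations:
        if o.censoring is not Censoring.NONE:
            ax.axvline(o.threshold_log10, color="tab:red", ls=":", lw=0.8)
    ax.axvspan(-1, 3, color="0.9", zorder=0)
    ax.axvline(float(np.mean(draws.mu)), color="tab:blue", ls="--", label="inferred mean")
    if values:
        ax.axvline(float(np.mean(values)), color="tab:orange", ls="--",
                   label="descriptive mean")
    ax.set_xlabel("log10 DT50 [log(d)]")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    return ax
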