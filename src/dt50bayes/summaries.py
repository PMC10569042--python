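"""Posterior and descriptive summaries, cohort comparison, persistence metrics.

Per substance the posterior draws are summarized by the posterior mean of
the average log half-life (mu_mean), its posterior standard deviation
(mu_std, the uncertainty of the mean), and the mean and sd of the
experimental variability (sigma_mean, sigma_std).  The descriptive
counterpart — mean, median, sample sd of the uncensored log10 values — is
computed alongside; the two approaches converge in the high-data regime
but the descriptive sd is undefined below two values and biased when data
are censored.

Persistence classification is probabilistic: a substance can be judged
against a regulatory half-life threshold either through the probability
that its *average* half-life exceeds the threshold (uses mu_std) or
through the posterior-predictive probability that a *single new
experiment* would exceed it (uses sigma_mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .censoring import Censoring, Observation
from .inference import PosteriorDraws


@dataclass
class PosteriorSummary:
    mu_mean: float
    mu_std: float
    sigma_mean: float
    sigma_std: float
    n_obs: int
    n_left: int
    n_right: int

    @property
    def n_uncensored(self) -> int:
        return self.n_obs - self.n_left - self.n_right


@dataclass
class DescriptiveSummary:
    """Mean/median/sd of uncensored log10 values; std is None below n=2."""

    mean: float
    median: float
    std: float | None
    n: int


def summarize_posterior(
    draws: PosteriorDraws, observations: Sequence[Observation]
) -> PosteriorSummary:
    """Mean/sd of the pooled post-burn-in draws plus censoring counts."""
    if len(draws) == 0:
        raise ValueError("cannot summarize empty posterior draws")
    n_left = sum(1 for o in observations if o.censoring is Censoring.LEFT)
    n_right = sum(1 for o in observations if o.censoring is Censoring.RIGHT)
    return PosteriorSummary(
        mu_mean=float(np.mean(draws.mu)),
        mu_std=float(np.std(draws.mu)),
        sigma_mean=float(np.mean(draws.sigma)),
        sigma_std=float(np.std(draws.sigma)),
        n_obs=len(observations),
        n_left=n_left,
        n_right=n_right,
    )


def summarize_descriptive(values_log10: Sequence[float]) -> DescriptiveSummary:
    """Descriptive statistics of log10 half-lives (n-1 denominator sd)."""
    values = np.asarray(list(values_log10), dtype=float)
    if values.size == 0:
        raise ValueError("descriptive summary requires at least one value")
    std = float(np.std(values, ddof=1)) if values.size >= 2 else None
    return DescriptiveSummary(
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        std=std,
        n=int(values.size),
    )


#: n-observation bins for the descriptive-vs-inferred sd comparison.
N_OBS_BINS: tuple[tuple[int, float], ...] = (
    (1, 1),
    (2, 2),
    (3, 5),
    (6, 10),
    (11, 20),
    (21, math.inf),
)


def _bin_label(n: int) -> str:
    for lo, hi in N_OBS_BINS:
        if lo <= n <= hi:
            return f"{lo}" if lo == hi else (f"{lo}+" if math.isinf(hi) else f"{lo}-{int(hi)}")
    return str(n)


def cohort_comparison(results: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Cohort-level comparison of the descriptive and inferred approaches.

    ``results`` is the per-substance results table (one row per compound
    with desc_mean/desc_std/mu_mean/sigma_mean/n_obs columns).  Returns the
    aggregate means over substances and a stratification of the
    descriptive-vs-inferred sd by number of observations.
    """
    if results.empty:
        raise ValueError("cohort comparison requires at least one substance")
    aggregates = {
        "n_substances": int(len(results)),
        "mean_desc_mean": float(results["desc_mean"].mean()),
        "mean_mu_mean": float(results["mu_mean"].mean()),
        "mean_desc_std": float(results["desc_std"].mean()),
        "mean_sigma_mean": float(results["sigma_mean"].mean()),
    }
    df = results.copy()
    df["n_bin"] = [_bin_label(int(n)) for n in df["n_obs"]]
    order = [_bin_label(lo) for lo, _ in N_OBS_BINS]
    strata = (
        df.groupby("n_bin")
        .agg(
            n_substances=("n_obs", "size"),
            mean_desc_std=("desc_std", "mean"),
            mean_sigma_mean=("sigma_mean", "mean"),
        )
        .reindex([b for b in order if b in set(df["n_bin"])])
        .reset_index()
    )
    strata["sd_gap"] = strata["mean_sigma_mean"] - strata["mean_desc_std"]
    return aggregates, strata


@dataclass
class PersistenceAssessment:
    """Two probabilistic persistence metrics against one threshold."""

    threshold_days: float
    p_mean_exceeds: float
    p_experiment_exceeds: float

    def nonpersistent_by_mean(self, level: float = 0.95) -> bool:
        """True if the average half-life lies below the threshold with
        probability >= level (uses the uncertainty of the mean)."""
        return (1.0 - self.p_mean_exceeds) >= level

    def nonpersistent_by_experiment(self, level: float = 0.95) -> bool:
        """True if a fraction >= level of experiments would indicate
        nonpersistence (uses the experimental variability)."""
        return (1.0 - self.p_experiment_exceeds) >= level


def persistence_assessment(
    draws: PosteriorDraws, threshold_days: float, sigma_min: float = 0.2
) -> PersistenceAssessment:
    """Posterior probabilities of exceeding a persistence threshold.

    ``p_mean_exceeds`` is the fraction of mu draws above log10(threshold);
    ``p_experiment_exceeds`` is the posterior-predictive probability that
    one new experiment reports a log10 DT50 above the threshold, averaging
    the normal tail probability with sd sigma + sigma_min over the draws.
    """
    if threshold_days <= 0:
        raise ValueError("threshold_days must be positive")
    t = math.log10(threshold_days)
    p_mean = float(np.mean(draws.mu > t))
    s = draws.sigma + sigma_min
    p_exp = float(np.mean(ndtr((draws.mu - t) / s)))
    return PersistenceAssessment(
        threshold_days=threshold_days,
        p_mean_exceeds=p_mean,
        p_experiment_exceeds=p_exp,
    )
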