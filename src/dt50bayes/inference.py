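"""Bayesian inference of per-substance half-life distributions.

Model: the log10 half-lives of substance *i* are
``x ~ Normal(mu_i, sigma_min + sigma_i)``, where ``sigma_min`` is the
minimal experimental variability common to all substances and ``sigma_i``
the substance-specific experimental noise.  Censored observations enter the
likelihood through the normal CDF (a Tobit-style censored likelihood): a
left-censored value at threshold *t* contributes ``Phi((t-mu)/s)``, a
right-censored one ``1 - Phi((t-mu)/s)``, with ``s = sigma_i + sigma_min``.

Priors: ``mu_i ~ Normal(1, 2)`` on the log10(days) scale (centered in the
measurable range -1..3 log(d)) and ``sigma_i ~ LogNormal`` with mean 0.4
and standard deviation 0.4 log(d), converted to the underlying-normal
location/scale by moment matching.

The posterior is sampled with an affine-invariant ensemble sampler
(Goodman & Weare stretch move), implemented here; defaults are 10 walkers,
2000 iterations, the first 100 iterations per walker discarded as burn-in.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import log_ndtr

from .censoring import Censoring, Observation

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for (mu_i, sigma_i), on the log10(days) scale.

    ``sigma_prior_mean`` and ``sigma_prior_sd`` are, by default, the mean
    and standard deviation of the log-normal variate sigma_i itself (their
    units, log(d), match sigma_i's); they are converted to the
    underlying-normal parameters by moment matching.  Set
    ``sigma_params_are_log_scale=True`` to read them directly as the
    underlying normal's location and scale instead.
    """

    mu_prior_mean: float = 1.0
    mu_prior_sd: float = 2.0
    sigma_prior_mean: float = 0.4
    sigma_prior_sd: float = 0.4
    sigma_params_are_log_scale: bool = False

    @property
    def sigma_log_scale(self) -> float:
        """Scale s_ln of the underlying normal of the log-normal prior."""
        if self.sigma_params_are_log_scale:
            return self.sigma_prior_sd
        m, s = self.sigma_prior_mean, self.sigma_prior_sd
        return math.sqrt(math.log1p((s / m) ** 2))

    @property
    def sigma_log_loc(self) -> float:
        """Location m_ln of the underlying normal of the log-normal prior."""
        if self.sigma_params_are_log_scale:
            return self.sigma_prior_mean
        return math.log(self.sigma_prior_mean) - 0.5 * self.sigma_log_scale**2


@dataclass(frozen=True)
class ModelConfig:
    """All model constants and sampler settings for one run."""

    sigma_min: float = 0.2
    prior: PriorSpec = field(default_factory=PriorSpec)
    n_walkers: int = 10
    n_iterations: int = 2000
    burn_in_iterations: int = 100
    stretch_a: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers < 4 or self.n_walkers % 2:
            raise ValueError("n_walkers must be even and >= 4 (2 x parameters)")
        if not 0 <= self.burn_in_iterations < self.n_iterations:
            raise ValueError("require 0 <= burn_in_iterations < n_iterations")
        if self.sigma_min < 0:
            raise ValueError("sigma_min must be nonnegative")
        if self.stretch_a <= 1:
            raise ValueError("stretch_a must exceed 1")


@dataclass
class PosteriorDraws:
    """Pooled post-burn-in draws of (mu, sigma) from all walkers."""

    mu: np.ndarray
    sigma: np.ndarray
    acceptance_fraction: float
    seed: int

    def __len__(self) -> int:
        return self.mu.size


def log_prior(
    mu: float | np.ndarray, sigma: float | np.ndarray, prior: PriorSpec
) -> float | np.ndarray:
    """Natural-log prior density; -inf for sigma outside (0, inf)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    m_ln, s_ln = prior.sigma_log_loc, prior.sigma_log_scale
    lp_mu = (
        -0.5 * ((mu - prior.mu_prior_mean) / prior.mu_prior_sd) ** 2
        - math.log(prior.mu_prior_sd)
        - _LOG_SQRT_2PI
    )
    ok = sigma > 0
    safe = np.where(ok, sigma, 1.0)
    log_sig = np.log(safe)
    lp_sigma = (
        -0.5 * ((log_sig - m_ln) / s_ln) ** 2
        - log_sig
        - math.log(s_ln)
        - _LOG_SQRT_2PI
    )
    out = np.where(ok, lp_mu + lp_sigma, -np.inf)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class _PackedObs:
    """Observation arrays, split by censoring status, for fast likelihoods."""

    x: np.ndarray        # uncensored log10 values
    t_left: np.ndarray   # left-censoring thresholds, log10
    t_right: np.ndarray  # right-censoring thresholds, log10

    @classmethod
    def from_observations(cls, observations: Sequence[Observation]) -> "_PackedObs":
        if not observations:
            raise ValueError("fitting requires at least one observation")
        x, tl, tr = [], [], []
        for o in observations:
            if o.censoring is Censoring.NONE:
                x.append(o.value_log10)
            elif o.censoring is Censoring.LEFT:
                tl.append(o.threshold_log10)
            else:
                tr.append(o.threshold_log10)
        return cls(
            x=np.asarray(x, dtype=float),
            t_left=np.asarray(tl, dtype=float),
            t_right=np.asarray(tr, dtype=float),
        )


def _log_likelihood_packed(
    obs: _PackedObs,
    mu: np.ndarray,
    sigma: np.ndarray,
    sigma_min: float,
) -> np.ndarray:
    """Vectorized censored-normal log likelihood over parameter vectors."""
    s = sigma + sigma_min
    ok = s > 0
    s_safe = np.where(ok, s, 1.0)
    ll = np.zeros(np.broadcast_shapes(np.shape(mu), np.shape(s)))
    if obs.x.size:
        z = (obs.x[:, None] - mu) / s_safe
        ll = ll - 0.5 * np.sum(z * z, axis=0) - obs.x.size * (np.log(s_safe) + _LOG_SQRT_2PI)
    if obs.t_left.size:
        ll = ll + np.sum(log_ndtr((obs.t_left[:, None] - mu) / s_safe), axis=0)
    if obs.t_right.size:
        ll = ll + np.sum(log_ndtr((mu - obs.t_right[:, None]) / s_safe), axis=0)
    return np.where(ok, ll, -np.inf)


def log_likelihood(
    observations: Sequence[Observation],
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
    sigma_min: float = 0.2,
) -> float | np.ndarray:
    """Censored-normal log likelihood with effective sd sigma + sigma_min.

    Uncensored x contributes the normal log density at x; a LEFT-censored
    observation at threshold t contributes log Phi((t-mu)/s); a
    RIGHT-censored one log(1 - Phi((t-mu)/s)), computed via the log-CDF for
    tail stability.
    """
    packed = _PackedObs.from_observations(observations)
    mu_a = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma_a = np.atleast_1d(np.asarray(sigma, dtype=float))
    out = _log_likelihood_packed(packed, mu_a, sigma_a, sigma_min)
    if np.isscalar(mu) or (isinstance(mu, np.ndarray) and mu.ndim == 0):
        return float(out[0])
    return out


def log_posterior(
    observations: Sequence[Observation],
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
    config: ModelConfig,
) -> float | np.ndarray:
    """log prior + log likelihood; -inf propagates from either term."""
    lp = log_prior(mu, sigma, config.prior)
    ll = log_likelihood(observations, mu, sigma, config.sigma_min)
    with np.errstate(invalid="ignore"):
        out = np.asarray(lp) + np.asarray(ll)
    # -inf + anything stays -inf (avoid nan from -inf + inf; ll never +inf)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Affine-invariant ensemble sampler (Goodman & Weare stretch move)


def _draw_from_prior(
    prior: PriorSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    mu = rng.normal(prior.mu_prior_mean, prior.mu_prior_sd, size=n)
    sigma = rng.lognormal(prior.sigma_log_loc, prior.sigma_log_scale, size=n)
    return np.column_stack([mu, sigma])


def init_walkers(
    log_density: Callable[[np.ndarray, np.ndarray], np.ndarray],
    config: ModelConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Initialize walkers from the prior, redrawing any at -inf density."""
    x = _draw_from_prior(config.prior, config.n_walkers, rng)
    for _ in range(max_retries):
        lp = log_density(x[:, 0], x[:, 1])
        bad = ~np.isfinite(lp)
        if not bad.any():
            return x
        x[bad] = _draw_from_prior(config.prior, int(bad.sum()), rng)
    raise RuntimeError("could not initialize walkers at finite density")


def run_ensemble_mcmc(
    log_density: Callable[[np.ndarray, np.ndarray], np.ndarray],
    config: ModelConfig,
    rng: np.random.Generator | int | None = None,
    initial: np.ndarray | None = None,
) -> PosteriorDraws:
    """Sample a 2-D density with the affine-invariant stretch move.

    ``log_density(mu, sigma)`` must accept equal-length 1-D arrays and
    return the log densities.  The ensemble is updated in two halves per
    iteration (each walker stretches along a line through a walker of the
    complementary half), which preserves detailed balance while allowing
    vectorized density evaluation.  Proposal ``y = x_k + z (x_j - x_k)``
    with ``z ~ g(z) \\propto 1/sqrt(z)`` on ``[1/a, a]`` is accepted with
    probability ``min(1, z^(d-1) exp(log_density(y) - log_density(x_j)))``
    for dimension d = 2.  Fully reproducible given the seed.
    """
    seed = config.seed if not isinstance(rng, (int, np.integer)) else int(rng)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(seed)
    nw, a = config.n_walkers, config.stretch_a
    if initial is None:
        x = init_walkers(log_density, config, rng)
    else:
        x = np.array(initial, dtype=float, copy=True)
        if x.shape != (nw, 2):
            raise ValueError(f"initial must have shape ({nw}, 2)")
    lp = np.asarray(log_density(x[:, 0], x[:, 1]), dtype=float)
    if not np.isfinite(lp).any():
        raise RuntimeError("all walkers start at -inf density")

    half = nw // 2
    chain = np.empty((config.n_iterations, nw, 2))
    n_accept = 0
    for it in range(config.n_iterations):
        for lo, hi, olo, ohi in ((0, half, half, nw), (half, nw, 0, half)):
            xs = x[lo:hi]
            xo = x[olo:ohi]
            z = (1.0 + (a - 1.0) * rng.random(half)) ** 2 / a
            partners = xo[rng.integers(0, ohi - olo, size=half)]
            prop = partners + z[:, None] * (xs - partners)
            lp_prop = np.asarray(log_density(prop[:, 0], prop[:, 1]), dtype=float)
            with np.errstate(invalid="ignore"):
                log_ratio = np.log(z) + lp_prop - lp[lo:hi]
            accept = np.log(rng.random(half)) < log_ratio
            xs[accept] = prop[accept]
            lp[lo:hi][accept] = lp_prop[accept]
            n_accept += int(accept.sum())
        chain[it] = x
    pooled = chain[config.burn_in_iterations :].reshape(-1, 2)
    return PosteriorDraws(
        mu=pooled[:, 0].copy(),
        sigma=pooled[:, 1].copy(),
        acceptance_fraction=n_accept / (config.n_iterations * nw),
        seed=seed,
    )


def derive_seed(global_seed: int, compound_key: str) -> int:
    """Stable per-substance seed from the global seed and the merge key.

    Hash-based so per-substance results are independent of processing
    order; kept below 2**31.
    """
    digest = hashlib.sha256(f"{global_seed}:{compound_key}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def fit_substance(
    observations: Sequence[Observation],
    config: ModelConfig,
    compound_key: str = "",
) -> PosteriorDraws:
    """Sample the posterior of (mu_i, sigma_i) for one substance.

    Censored-only observation sets are valid input: the censored likelihood
    still constrains mu, which is how substances with no quantified
    half-life at all retain a meaningful estimate.
    """
    packed = _PackedObs.from_observations(observations)
    prior = config.prior

    def density(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        lp = log_prior(mu, sigma, prior)
        ll = _log_likelihood_packed(packed, mu, sigma, config.sigma_min)
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(lp), lp + ll, -np.inf)

    seed = derive_seed(config.seed, compound_key)
    rng = np.random.default_rng(seed)
    per_substance = replace(config, seed=seed)
    return run_ensemble_mcmc(density, per_substance, rng)


@dataclass
class SigmaMinEstimate:
    """Reference-compound estimate of the minimal experimental variability."""

    n_reference: int
    per_compound_sd: dict[str, float]
    mean_sd: float | None


def estimate_sigma_min(compounds, min_points: int = 20) -> SigmaMinEstimate:
    """Mean log10 sd over reference compounds with > min_points uncensored values.

    The result supports choosing sigma_min; if no compound qualifies the
    estimate is empty and the configured default applies.
    """
    per: dict[str, float] = {}
    for c in compounds:
        values = [
            o.value_log10 for o in c.observations if o.censoring is Censoring.NONE
        ]
        if len(values) > min_points:
            per[c.canonical_smiles] = float(np.std(values, ddof=1))
    mean_sd = float(np.mean(list(per.values()))) if per else None
    return SigmaMinEstimate(n_reference=len(per), per_compound_sd=per, mean_sd=mean_sd)
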