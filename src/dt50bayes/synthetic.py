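"""Synthetic half-life record generator with known ground truth.

Emulates the statistical structure the analysis assumes: each simulated
substance i has a true average log10 half-life mu_i drawn from
Normal(1, 2) and an experimental noise sigma_i drawn from the log-normal
with mean 0.4 and sd 0.4 log(d) (the same distributions used as priors),
and its reported log10 half-lives are Normal(mu_i, sigma_i + sigma_min)
draws.  Sample sizes per substance span 1-60 with most substances data
poor, mirroring a regulatory-report export in which many compounds carry
only one or two values and a few reference compounds carry dozens.

Values falling outside the global quantification range (0.1-1000 days) are
written verbatim — classifying them is the censoring module's job.  A
small fraction of records passes through a simulated assay window: when
the drawn value falls beyond a record-local reporting limit, the record
carries only a comment bound (e.g. ">365 days") instead of a point value,
in one of several comment dialects to exercise the parser.

Truth tables are written alongside the records for parameter-recovery
tests; the analysis pipeline never reads them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curation import RawRecord

#: Comment dialects for right and left bounds; {v} is the bound in days.
_RIGHT_DIALECTS = (">{v}", "> {v} days", "≥ {v}", "> {v} d")
_LEFT_DIALECTS = ("<{v}", "< {v} days", "≤ {v}", "< {v} d")

#: Decoy records exercising curation: a sodium-acetate salt, an enantiomer
#: pair that must merge, a two-active-component mixture that must be
#: dropped, and an unparseable SMILES.
_DECOYS = (
    ("decoy-salt", "sodium acetate", "CC(=O)[O-].[Na+]", 5.0, ""),
    ("decoy-ent-R", "alanine (R)", "C[C@H](N)C(=O)O", 2.0, ""),
    ("decoy-ent-S", "alanine (S)", "C[C@@H](N)C(=O)O", 4.0, ""),
    ("decoy-mixture", "benzene + ethylamine", "c1ccccc1.CCN", 10.0, ""),
    ("decoy-badsmiles", "not a structure", "this_is_not_smiles", 1.0, ""),
)


def _default_n_obs_distribution() -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Discrete sample-size mix over 1-60: 45% in {1,2}, 45% in 3-15,
    10% in 16-60 (reference-grade compounds)."""
    ns, ps = [], []
    for n in (1, 2):
        ns.append(n)
        ps.append(0.45 / 2)
    for n in range(3, 16):
        ns.append(n)
        ps.append(0.45 / 13)
    for n in range(16, 61):
        ns.append(n)
        ps.append(0.10 / 45)
    return tuple(ns), tuple(ps)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of one simulated substance."""

    compound_id: str
    compound_key: str  # canonical SMILES, the post-curation merge key
    true_mu: float
    true_sigma: float
    n_obs: int
    expected_left: float
    expected_right: float


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator; defaults mirror the inference model."""

    n_compounds: int = 50
    mu_mean: float = 1.0
    mu_sd: float = 2.0
    sigma_mean: float = 0.4
    sigma_sd: float = 0.4
    sigma_min: float = 0.2
    global_low_days: float = 0.1
    global_high_days: float = 1000.0
    #: probability that a record passes through a local assay window
    local_window_rate: float = 0.05
    #: among windowed records, probability the window is a lower limit
    local_window_left_frac: float = 0.85
    #: log10-day ranges the local limits are drawn from (within the global range)
    local_low_limit_range: tuple[float, float] = (-0.7, 0.7)
    local_high_limit_range: tuple[float, float] = (1.5, 2.95)
    n_obs_values: tuple[int, ...] = field(
        default_factory=lambda: _default_n_obs_distribution()[0]
    )
    n_obs_probs: tuple[float, ...] = field(
        default_factory=lambda: _default_n_obs_distribution()[1]
    )
    include_decoys: bool = False
    seed: int = 0

    @property
    def sigma_log_scale(self) -> float:
        return math.sqrt(math.log1p((self.sigma_sd / self.sigma_mean) ** 2))

    @property
    def sigma_log_loc(self) -> float:
        return math.log(self.sigma_mean) - 0.5 * self.sigma_log_scale**2

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not 0 <= self.local_window_rate <= 1:
            raise ValueError("local_window_rate must lie in [0, 1]")
        if self.sigma_mean <= 0 or self.sigma_sd <= 0:
            raise ValueError("sigma distribution parameters must be positive")
        if abs(sum(self.n_obs_probs) - 1.0) > 1e-9:
            raise ValueError("n_obs_probs must sum to 1")


def _compound_smiles(index: int) -> str:
    """Distinct, RDKit-parseable structure per index (a linear alkanol)."""
    return "C" * (index + 1) + "O"


def expected_censoring(
    true_mu: float, true_sigma: float, config: GeneratorConfig
) -> tuple[float, float]:
    """Per-record probabilities of global left / right censoring."""
    from scipy.special import ndtr

    s = true_sigma + config.sigma_min
    lo = math.log10(config.global_low_days)
    hi = math.log10(config.global_high_days)
    return float(ndtr((lo - true_mu) / s)), float(1.0 - ndtr((hi - true_mu) / s))


def generate_compound(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[RawRecord]:
    """Draw the raw records of one simulated substance.

    A record subjected to a local assay window reports only a comment
    bound when the drawn value falls beyond the window limit — proper
    censoring, since the limit is drawn independently of the value.
    """
    s = truth.true_sigma + config.sigma_min
    if not (s > 0) or not math.isfinite(s):
        raise ValueError(f"invalid total sd {s!r}")
    x = rng.normal(truth.true_mu, s, size=truth.n_obs)
    records = []
    for j, xj in enumerate(x):
        record_id = f"{truth.compound_id}-r{j:03d}"
        value: float | None = float(10.0**xj)
        comment = ""
        if rng.random() < config.local_window_rate:
            if rng.random() < config.local_window_left_frac:
                limit = rng.uniform(*config.local_low_limit_range)
                if xj < limit:
                    value = None
                    dialect = _LEFT_DIALECTS[rng.integers(len(_LEFT_DIALECTS))]
                    comment = dialect.format(v=f"{10.0 ** limit:.4g}")
            else:
                limit = rng.uniform(*config.local_high_limit_range)
                if xj > limit:
                    value = None
                    dialect = _RIGHT_DIALECTS[rng.integers(len(_RIGHT_DIALECTS))]
                    comment = dialect.format(v=f"{10.0 ** limit:.4g}")
        records.append(
            RawRecord(
                compound_id=record_id,
                compound_name=f"synthetic-{truth.compound_id}",
                smiles=truth.compound_key,
                halflife_days=value,
                comment=comment,
            )
        )
    return records


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a raw record table and the matching truth table.

    Record order is randomized; identical seeds give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truths: list[SyntheticTruth] = []
    all_records: list[RawRecord] = []
    n_choices = np.asarray(config.n_obs_values)
    p_choices = np.asarray(config.n_obs_probs)
    for i in range(config.n_compounds):
        mu = rng.normal(config.mu_mean, config.mu_sd)
        sigma = rng.lognormal(config.sigma_log_loc, config.sigma_log_scale)
        n_obs = int(rng.choice(n_choices, p=p_choices))
        truth = SyntheticTruth(
            compound_id=f"cpd-{i:04d}",
            compound_key=_compound_smiles(i),
            true_mu=float(mu),
            true_sigma=float(sigma),
            n_obs=n_obs,
            expected_left=0.0,
            expected_right=0.0,
        )
        p_left, p_right = expected_censoring(truth.true_mu, truth.true_sigma, config)
        truth = replace(
            truth, expected_left=p_left * n_obs, expected_right=p_right * n_obs
        )
        truths.append(truth)
        all_records.extend(generate_compound(truth, config, rng))
    if config.include_decoys:
        for cid, name, smiles, days, comment in _DECOYS:
            all_records.append(
                RawRecord(
                    compound_id=cid,
                    compound_name=name,
                    smiles=smiles,
                    halflife_days=days,
                    comment=comment,
                )
            )
    order = rng.permutation(len(all_records))
    records_df = pd.DataFrame(
        {
            "compound_id": [all_records[k].compound_id for k in order],
            "compound_name": [all_records[k].compound_name for k in order],
            "smiles": [all_records[k].smiles for k in order],
            "halflife_days": [all_records[k].halflife_days for k in order],
            "comment": [all_records[k].comment for k in order],
        }
    )
    truth_df = pd.DataFrame(
        {
            "compound_id": [t.compound_id for t in truths],
            "compound_key": [t.compound_key for t in truths],
            "true_mu": [t.true_mu for t in truths],
            "true_sigma": [t.true_sigma for t in truths],
            "n_obs": [t.n_obs for t in truths],
            "expected_left": [t.expected_left for t in truths],
            "expected_right": [t.expected_right for t in truths],
        }
    )
    return records_df, truth_df
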