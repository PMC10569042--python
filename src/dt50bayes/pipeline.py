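"""End-to-end orchestration: cohort fitting and stage I/O used by the CLI."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .censoring import Censoring, CensoringConfig
from .curation import (
    Compound,
    compounds_frame,
    compounds_from_frames,
    curate,
    observations_frame,
    read_records,
)
from .inference import ModelConfig, PriorSpec, fit_substance
from .summaries import persistence_assessment, summarize_descriptive, summarize_posterior

logger = logging.getLogger(__name__)


def fit_cohort(
    compounds: list[Compound],
    config: ModelConfig,
    threshold_days: float | None = None,
) -> pd.DataFrame:
    """Fit every compound and return the per-substance results table.

    Substances with only censored observations are fitted like any other;
    compounds with zero observations are skipped with a warning.  Results
    are deterministic given ``config.seed`` and independent of compound
    order (per-substance seeds derive from the merge key).
    """
    rows = []
    for c in compounds:
        if not c.observations:
            logger.warning("compound %s has no observations; skipped", c.canonical_smiles)
            continue
        draws = fit_substance(c.observations, config, compound_key=c.canonical_smiles)
        post = summarize_posterior(draws, c.observations)
        uncensored = [
            o.value_log10 for o in c.observations if o.censoring is Censoring.NONE
        ]
        desc = summarize_descriptive(uncensored) if uncensored else None
        row = {
            "canonical_smiles": c.canonical_smiles,
            "inchikey": c.inchikey,
            "name": c.display_name,
            "n_obs": post.n_obs,
            "n_left": post.n_left,
            "n_right": post.n_right,
            "desc_mean": desc.mean if desc else np.nan,
            "desc_median": desc.median if desc else np.nan,
            "desc_std": desc.std if desc and desc.std is not None else np.nan,
            "mu_mean": post.mu_mean,
            "mu_std": post.mu_std,
            "sigma_mean": post.sigma_mean,
            "sigma_std": post.sigma_std,
        }
        if threshold_days is not None:
            pa = persistence_assessment(draws, threshold_days, config.sigma_min)
            row["p_mean_exceeds"] = pa.p_mean_exceeds
            row["p_experiment_exceeds"] = pa.p_experiment_exceeds
        rows.append(row)
    return pd.DataFrame(rows)


def model_config_from_dict(raw: dict) -> ModelConfig:
    """Build a ModelConfig (with nested PriorSpec) from a plain mapping."""
    raw = dict(raw or {})
    prior = PriorSpec(**raw.pop("prior", {}))
    return ModelConfig(prior=prior, **raw)


def censoring_config_from_dict(raw: dict) -> CensoringConfig:
    raw = dict(raw or {})
    if "extra_patterns" in raw:
        raw["extra_patterns"] = tuple(raw["extra_patterns"])
    return CensoringConfig(**raw)


def run_curate(
    input_path: str | Path,
    outdir: str | Path,
    censoring_config: CensoringConfig | None = None,
) -> dict:
    """Curate one raw table into compound/observation tables plus a report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        records = read_records(input_path)
    except pd.errors.EmptyDataError:
        logger.warning("input file %s is empty", input_path)
        records = []
    compounds, report = curate(records, censoring_config)
    compounds_frame(compounds).to_csv(outdir / "compounds.tsv", sep="\t", index=False)
    observations_frame(compounds).to_csv(
        outdir / "observations.tsv", sep="\t", index=False
    )
    report_dict = report.to_dict()
    (outdir / "curation_report.json").write_text(json.dumps(report_dict, indent=2))
    return report_dict


def load_curated(indir: str | Path) -> list[Compound]:
    indir = Path(indir)
    compounds_df = pd.read_csv(indir / "compounds.tsv", sep="\t")
    observations_df = pd.read_csv(indir / "observations.tsv", sep="\t")
    return compounds_from_frames(compounds_df, observations_df)


def run_fit(
    indir: str | Path,
    outdir: str | Path,
    config: ModelConfig,
    threshold_days: float | None = None,
) -> pd.DataFrame:
    """Fit a curated directory and write results.tsv plus a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds = load_curated(indir)
    results = fit_cohort(compounds, config, threshold_days)
    results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    echo = {"model": asdict(config), "threshold_days": threshold_days}
    (outdir / "fit_config.json").write_text(json.dumps(echo, indent=2))
    return results
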