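"""Shared fixtures: small curation tables and fast model configurations."""

from __future__ import annotations

import numpy as np
import pytest

from dt50bayes import ModelConfig, Observation, RawRecord


@pytest.fixture
def model_config() -> ModelConfig:
    """Default model settings (10 walkers, 2000 iterations, burn-in 100)."""
    return ModelConfig(seed=1234)


@pytest.fixture
def ten_record_fixture() -> list[RawRecord]:
    """Ten raw records exercising every curation rule.

    Contains one salt (whose active part duplicates a plain record), one
    two-active-component mixture (dropped), and an enantiomer pair
    (merged), so the expected curated set has exactly 7 compounds and 9
    observations.
    """

    def rec(i, name, smiles, hl, comment=""):
        return RawRecord(
            compound_id=f"r{i}",
            compound_name=name,
            smiles=smiles,
            halflife_days=hl,
            comment=comment,
        )

    return [
        rec(1, "ethanol", "CCO", 1.0),
        rec(2, "propanol", "CCCO", 2.0),
        rec(3, "butanol", "CCCCO", 3.0),
        rec(4, "acetate", "CC(=O)[O-]", 4.0),
        rec(5, "sodium acetate", "CC(=O)[O-].[Na+]", 5.0),
        rec(6, "benzene + ethylamine", "c1ccccc1.CCN", 6.0),
        rec(7, "alanine (R)", "C[C@H](N)C(=O)O", 7.0),
        rec(8, "alanine (S)", "C[C@@H](N)C(=O)O", 8.0),
        rec(9, "benzene", "c1ccccc1", 9.0),
        rec(10, "ethylamine", "CCN", 10.0),
    ]


def make_uncensored(values, prefix="obs") -> list[Observation]:
    return [
        Observation(source_record_id=f"{prefix}{i}", value_log10=float(v))
        for i, v in enumerate(values)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
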