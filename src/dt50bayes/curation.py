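"""Curation of raw half-life record tables into a deduplicated compound set.

A raw export carries one row per reported experiment: a compound identifier
and name, a SMILES (possibly a salt with counterions, possibly with
stereochemistry), the half-life in days and a free-text comment.  Curation

* strips counterions from salt entries, keeping the single active
  component (entries with two or more distinct active components are
  removed — mixtures are out of scope);
* merges stereoisomers and duplicates on canonical SMILES with
  stereochemistry removed, concatenating their observation lists and
  keeping all names as synonyms;
* converts half-lives to log10(days) and attaches censoring status.

Record-level failures (unparseable SMILES, nonpositive half-life, no value
and no bound) skip the record with a logged reason; they never abort a run.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger

from .censoring import Censoring, CensoringConfig, Observation, classify

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")


class CurationError(ValueError):
    """A record-level curation failure (bad SMILES, bad value ...)."""


class _Removed:
    """Sentinel: entry removed because several active components remain."""

    def __repr__(self) -> str:  # pragma: no cover
        return "REMOVED"


REMOVED = _Removed()

#: Default counterion list: alkali / alkaline-earth cations, halides,
#: ammonium, hydroxide, water, and common inorganic oxyanions.  Configurable
#: because the set of non-active salt components is a judgement call; every
#: stripped component is logged for audit.
DEFAULT_COUNTERIONS: frozenset[str] = frozenset(
    {
        "[Li+]", "[Na+]", "[K+]", "[Rb+]", "[Cs+]",
        "[Mg+2]", "[Ca+2]", "[Sr+2]", "[Ba+2]", "[Zn+2]",
        "[NH4+]",
        "[F-]", "[Cl-]", "[Br-]", "[I-]",
        "[OH-]", "O",
        "O=S(=O)([O-])[O-]", "O=S(=O)(O)[O-]",        # sulfate, bisulfate
        "O=[N+]([O-])[O-]",                            # nitrate
        "O=P([O-])([O-])[O-]", "O=P(O)([O-])[O-]", "O=P(O)(O)[O-]",
        "O=C([O-])[O-]", "O=C(O)[O-]",                 # carbonate, bicarbonate
    }
)


@dataclass
class RawRecord:
    """One reported half-life experiment as exported from the database."""

    compound_id: str
    compound_name: str
    smiles: str
    halflife_days: float | None
    comment: str = ""
    kinetic_model: str = ""
    study_name: str = ""
    metadata: dict = field(default_factory=dict)


@dataclass
class Compound:
    """A curated structure with all its merged observations."""

    canonical_smiles: str
    inchikey: str
    names: list[str]
    observations: list[Observation]

    @property
    def display_name(self) -> str:
        return self.names[0] if self.names else ""


@dataclass
class CurationReport:
    """Counts and audit trail for one curation run."""

    n_records_in: int = 0
    n_records_kept: int = 0
    n_dropped: Counter = field(default_factory=Counter)
    n_compounds_out: int = 0
    n_observations_out: int = 0
    stripped_components: list[tuple[str, str]] = field(default_factory=list)
    dropped_records: list[tuple[str, str]] = field(default_factory=list)

    def conserved(self) -> bool:
        """Observations out == records in minus records dropped."""
        return self.n_records_in == self.n_records_kept + sum(self.n_dropped.values())

    def to_dict(self) -> dict:
        return {
            "n_records_in": self.n_records_in,
            "n_records_kept": self.n_records_kept,
            "n_dropped": dict(self.n_dropped),
            "n_compounds_out": self.n_compounds_out,
            "n_observations_out": self.n_observations_out,
            "stripped_components": self.stripped_components,
            "dropped_records": self.dropped_records,
        }


def canonical_key(smiles: str) -> str:
    """Canonical SMILES with stereochemistry removed.

    Deterministic and idempotent; the merge key for deduplication.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def inchikey(smiles: str) -> str:
    """InChIKey of the (stereo-stripped) structure, for identification."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    try:
        return Chem.MolToInchiKey(mol)
    except Exception:  # pragma: no cover - inchi failures on exotic structures
        return ""


def strip_salts(
    smiles: str, counterion_list: frozenset[str] | set[str] = DEFAULT_COUNTERIONS
) -> str | _Removed:
    """Remove non-active salt components, keeping the single active part.

    Components matching the counterion list (compared on canonical,
    stereo-free SMILES) are dropped.  If exactly one distinct active
    component remains it is returned; if two or more distinct active
    components remain the entry is a mixture and ``REMOVED`` is returned.
    """
    counterion_keys = {canonical_key(c) for c in counterion_list}
    parts = [p for p in smiles.split(".") if p]
    if not parts:
        raise CurationError(f"empty SMILES: {smiles!r}")
    active: dict[str, str] = {}
    stripped: list[str] = []
    for part in parts:
        key = canonical_key(part)
        if key in counterion_keys:
            stripped.append(part)
        else:
            active.setdefault(key, part)
    if not active:
        raise CurationError(f"no active component left in {smiles!r}")
    if len(active) > 1:
        return REMOVED
    return next(iter(active.values()))


def to_log10_days(halflife_days: float) -> float:
    """Convert a half-life in days to log10 units."""
    if not halflife_days > 0:
        raise CurationError(f"nonpositive half-life: {halflife_days!r}")
    return math.log10(halflife_days)


def curate(
    records: list[RawRecord],
    censoring_config: CensoringConfig | None = None,
    counterion_list: frozenset[str] | set[str] = DEFAULT_COUNTERIONS,
) -> tuple[list[Compound], CurationReport]:
    """Run the full curation pipeline on parsed raw records.

    Returns the curated compounds (sorted by canonical SMILES, so the
    result is independent of input record order) and a report with all
    counts and the audit trail of dropped records and stripped components.
    """
    censoring_config = censoring_config or CensoringConfig()
    report = CurationReport(n_records_in=len(records))
    if not records:
        logger.warning("curate called with an empty record list")
        return [], report

    groups: dict[str, dict] = {}
    for rec in records:
        try:
            if not rec.smiles:
                raise CurationError("missing SMILES")
            active = strip_salts(rec.smiles, counterion_list)
            if active is REMOVED:
                report.n_dropped["multiple_active_components"] += 1
                report.dropped_records.append(
                    (rec.compound_id, "multiple_active_components")
                )
                continue
            if active != rec.smiles:
                for part in rec.smiles.split("."):
                    if part and part != active:
                        report.stripped_components.append((rec.compound_id, part))
            key = canonical_key(active)
            value = rec.halflife_days
            if value is not None and not value > 0:
                raise CurationError("nonpositive half-life")
            obs = classify(
                value,
                rec.comment,
                censoring_config,
                source_record_id=rec.compound_id,
            )
        except (CurationError, ValueError) as exc:
            reason = "no_halflife" if "neither" in str(exc) else "invalid_record"
            report.n_dropped[reason] += 1
            report.dropped_records.append((rec.compound_id, str(exc)))
            logger.info("dropped record %s: %s", rec.compound_id, exc)
            continue
        grp = groups.setdefault(key, {"names": set(), "observations": []})
        if rec.compound_name:
            grp["names"].add(rec.compound_name)
        grp["observations"].append(obs)
        report.n_records_kept += 1

    if report.n_records_in and not groups:
        raise CurationError("all input records were invalid")

    compounds = [
        Compound(
            canonical_smiles=key,
            inchikey=inchikey(key),
            names=sorted(grp["names"]),
            observations=grp["observations"],
        )
        for key, grp in sorted(groups.items())
    ]
    report.n_compounds_out = len(compounds)
    report.n_observations_out = sum(len(c.observations) for c in compounds)
    return compounds, report


# ---------------------------------------------------------------------------
# Table I/O

REQUIRED_COLUMNS = ("compound_id", "compound_name", "smiles", "halflife_days", "comment")


def read_records(path: str | Path) -> list[RawRecord]:
    """Read a raw record table (CSV or TSV, by extension) into RawRecords."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurationError(f"input table misses required columns: {missing}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[RawRecord]:
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        hl = d.get("halflife_days")
        records.append(
            RawRecord(
                compound_id=str(d["compound_id"]),
                compound_name="" if pd.isna(d["compound_name"]) else str(d["compound_name"]),
                smiles="" if pd.isna(d["smiles"]) else str(d["smiles"]),
                halflife_days=None if hl is None or pd.isna(hl) else float(hl),
                comment="" if pd.isna(d.get("comment")) else str(d["comment"]),
                kinetic_model=str(d.get("kinetic_model") or ""),
                study_name=str(d.get("study_name") or ""),
                metadata={k: d[k] for k in extra if k not in ("kinetic_model", "study_name")},
            )
        )
    return records


def compounds_frame(compounds: list[Compound]) -> pd.DataFrame:
    """Curated compound table: one row per merged structure."""
    return pd.DataFrame(
        {
            "canonical_smiles": [c.canonical_smiles for c in compounds],
            "inchikey": [c.inchikey for c in compounds],
            "names": ["|".join(c.names) for c in compounds],
            "n_observations": [len(c.observations) for c in compounds],
        }
    )


def observations_frame(compounds: list[Compound]) -> pd.DataFrame:
    """Curated observation table with censoring columns."""
    rows = []
    for c in compounds:
        for o in c.observations:
            rows.append(
                {
                    "canonical_smiles": c.canonical_smiles,
                    "source_record_id": o.source_record_id,
                    "log10_dt50": o.value_log10,
                    "censoring": o.censoring.value,
                    "threshold_log10": o.threshold_log10,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_smiles",
            "source_record_id",
            "log10_dt50",
            "censoring",
            "threshold_log10",
        ],
    )


def compounds_from_frames(
    compounds_df: pd.DataFrame, observations_df: pd.DataFrame
) -> list[Compound]:
    """Rebuild Compound objects from the curated tables."""
    obs_by_key: dict[str, list[Observation]] = {}
    for row in observations_df.itertuples(index=False):
        v = None if pd.isna(row.log10_dt50) else float(row.log10_dt50)
        t = None if pd.isna(row.threshold_log10) else float(row.threshold_log10)
        obs_by_key.setdefault(row.canonical_smiles, []).append(
            Observation(
                source_record_id=str(row.source_record_id),
                value_log10=v,
                censoring=Censoring(row.censoring),
                threshold_log10=t,
            )
        )
    compounds = []
    for row in compounds_df.itertuples(index=False):
        obs = obs_by_key.get(row.canonical_smiles, [])
        if not obs:
            logger.warning(
                "compound %s has no observations; skipped", row.canonical_smiles
            )
            continue
        names = [n for n in str(row.names).split("|") if n] if not pd.isna(row.names) else []
        compounds.append(
            Compound(
                canonical_smiles=row.canonical_smiles,
                inchikey="" if pd.isna(row.inchikey) else str(row.inchikey),
                names=names,
                observations=obs,
            )
        )
    return compounds
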