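"""Documented stub for the enviPath extraction workflow.

This package consumes an already-exported record table; it performs no
network access.  The upstream extraction of soil half-lives from the
public EAWAG-SOIL package on enviPath is documented here so a user with
network access can reproduce the export themselves.
"""

from __future__ import annotations

EAWAG_SOIL_PACKAGE = (
    "https://envipath.org/package/5882df9c-dae1-4d80-a40e-db4724271456"
)


def fetch_eawag_soil(*args, **kwargs):
    """Not implemented: extraction from the live enviPath database.

    The workflow, which this package deliberately does not perform:

    1. Query the EAWAG-SOIL package (see ``EAWAG_SOIL_PACKAGE``) through
       the enviPath Python API, iterating over all compound entries.
    2. For every compound, collect each reported soil half-life together
       with its metadata (study name, kinetic model, comment on the
       half-life, SMILES of the spiked compound, pH, CEC, organic carbon
       content, biomass at start/end, temperature, water storage type and
       value, humidity, soil texture); skip compound entries with no
       associated half-life.
    3. Write one row per reported half-life to a CSV/TSV with at least
       the columns ``compound_id, compound_name, smiles, halflife_days,
       comment`` — the input contract of :func:`dt50bayes.read_records`.

    Raises ``NotImplementedError`` always.
    """
    raise NotImplementedError(
        "Live enviPath extraction is outside this package's scope; export a "
        "record table with the enviPath API and feed it to read_records()."
    )
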