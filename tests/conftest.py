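"""Shared fixtures: tiny interactomes and localization tables."""

import pytest

from locpath import (
    CYTOSOL,
    EXTMEM,
    NUCLEUS,
    CompartmentModel,
    Interactome,
    LocalizationTable,
)


@pytest.fixture
def model():
    return CompartmentModel.default()


@pytest.fixture
def diamond():
    """S->A/B->C->T diamond with an A->T shortcut; used for ranked-path
    examples (scores 0.25, 0.25, 0.125 for the three best S-T paths)."""
    return Interactome.from_edges(
        [
            ("S", "A", 0.5),
            ("S", "B", 0.5),
            ("A", "C", 0.5),
            ("B", "C", 0.5),
            ("A", "T", 0.25),
            ("C", "T", 1.0),
        ]
    )


@pytest.fixture
def worked_table():
    """Three-protein localization table for the worked dynamic-program
    instance: optimal signaling cost -ln(0.25)."""
    return LocalizationTable(
        {
            "A": {EXTMEM: 1.0, CYTOSOL: 0.5, NUCLEUS: 0.0},
            "B": {EXTMEM: 0.25, CYTOSOL: 1.0, NUCLEUS: 0.5},
            "C": {EXTMEM: 0.0, CYTOSOL: 0.5, NUCLEUS: 1.0},
        }
    )


@pytest.fixture
def all_ones_table():
    return LocalizationTable(
        {p: {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0} for p in "ABCDEFGH"}
    )
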