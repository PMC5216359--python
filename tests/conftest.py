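import pytest

from barcodeauth.seqio import Alignment, SampleTable, SequenceRecord
from barcodeauth.simulate import SyntheticConfig, simulate_library

import pandas as pd


@pytest.fixture(scope="session")
def default_library():
    """The default synthetic study library (seed 1): records, table, truth."""
    return simulate_library(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_library():
    """A reduced library for expensive closed-loop checks."""
    cfg = SyntheticConfig(seed=1, n_congener_species=4, n_adulterant_species=3,
                          samples_per_species=2)
    return simulate_library(cfg)


def make_alignment(rows: dict[str, str], species: dict[str, str] | None = None) -> Alignment:
    species = species or {}
    return Alignment([SequenceRecord(i, s, species=species.get(i, ""))
                      for i, s in rows.items()])


def make_table(mapping: dict[str, tuple[str, str]]) -> SampleTable:
    """mapping: sample_id -> (species, group)."""
    return SampleTable(pd.DataFrame(
        [{"sample_id": sid, "species": sp, "group": grp}
         for sid, (sp, grp) in mapping.items()]
    ))
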