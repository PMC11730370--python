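import numpy as np
import pandas as pd
import pytest

from gutdyn.synthetic_cohort import SimConfig, generate_cohort
from gutdyn.tables_io import CountTable, SampleMetadata


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests."""
    return SimConfig(n_mice_tolerant=4, n_mice_nontolerant=3, n_taxa=60,
                     depth_mean=5_000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture
def toy_table():
    """4 samples x 3 taxa with full lineage."""
    lineage = {
        "taxA": {"kingdom": "Bacteria", "phylum": "Firmicutes",
                 "class": None, "order": None, "family": "famA",
                 "genus": "genA"},
        "taxB": {"kingdom": "Bacteria", "phylum": "Firmicutes",
                 "class": None, "order": None, "family": "famA",
                 "genus": "genA"},
        "taxC": {"kingdom": "Bacteria", "phylum": "Bacteroidetes",
                 "class": None, "order": None, "family": "famC",
                 "genus": None},
    }
    return CountTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        taxon_ids=["taxA", "taxB", "taxC"],
        counts=np.array([[3, 4, 0],
                         [1, 0, 2],
                         [5, 5, 5],
                         [0, 1, 9]]),
        lineage=lineage,
    )


@pytest.fixture
def toy_metadata():
    rows = []
    for i, (phase, week) in enumerate(
            [("pre", 0), ("pre", 1), ("mid", 8), ("mid", 9)]):
        rows.append(dict(sample_id=f"s{i+1}", mouse_id="m1", week=week,
                         phase=phase, tolerance="tolerant", batch="run0",
                         cohort="toy"))
    return SampleMetadata(pd.DataFrame(rows))
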