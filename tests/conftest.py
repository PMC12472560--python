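import numpy as np
import pandas as pd
import pytest

import myconet as mc


@pytest.fixture(scope="session")
def standard_dataset():
    """The package's standard three-treatment fixture (seed 0): dense CF,
    intermediate CK, sparse cooperation-dominated BF."""
    design = mc.treatment_effect_design(seed=0)
    table, taxonomy, metadata, guild_ref = mc.generate_dataset(design)
    return design, table, taxonomy, metadata, guild_ref


@pytest.fixture
def tiny_table():
    """Hand-written 3-taxon, 4-sample count table."""
    counts = pd.DataFrame(
        [[10, 20, 30, 40], [40, 30, 20, 10], [5, 5, 5, 5]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return mc.AsvTable(counts)


@pytest.fixture
def two_group_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "treatment": ["CK", "CK", "BF", "BF"],
        }
    )
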