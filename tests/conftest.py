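import numpy as np
import pandas as pd
import pytest

from dysbiome import (AbundanceTable, SampleMetadata, default_escc_config,
                      simulate_cohort)


@pytest.fixture
def toy_table():
    """4 samples x 3 taxa with genus/phylum lineages."""
    data = pd.DataFrame(
        [[5, 3, 2], [1, 0, 9], [4, 4, 4], [0, 7, 3]],
        index=["PN_1", "PN_2", "T_1", "T_2"],
        columns=["tax_a", "tax_b", "tax_c"],
    )
    lineages = {
        "tax_a": ("Bacteria", "Firmicutes", None, None, None, "Streptococcus", None),
        "tax_b": ("Bacteria", "Firmicutes", None, None, None, "Veillonella", None),
        "tax_c": ("Bacteria", "Proteobacteria", None, None, None, "Klebsiella", None),
    }
    return AbundanceTable(data, lineages)


@pytest.fixture
def toy_metadata():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["PN_1", "PN_2", "T_1", "T_2"],
        "group": ["PN", "PN", "T", "T"],
        "age": [44, 51, 63, 58],
    }))


@pytest.fixture(scope="session")
def default_cohort():
    """One default ESCC-like simulated cohort, shared across tests."""
    return simulate_cohort(default_escc_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
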