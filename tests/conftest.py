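import numpy as np
import pandas as pd
import pytest

import mrphewas as mp
from mrphewas.pipeline import _bundled


@pytest.fixture(scope="session")
def panel():
    return mp.default_panel()


@pytest.fixture(scope="session")
def toy_edges():
    return _bundled("toy_icd10_tree.csv")


@pytest.fixture(scope="session")
def toy_map():
    return mp.PhecodeMap(_bundled("toy_phecode_map.csv"))


@pytest.fixture(scope="session")
def cohort(panel, toy_edges):
    """A mid-size null cohort with two mapped outcomes and background codes."""
    config = mp.SimConfig(
        n_individuals=4000,
        panel=panel,
        outcomes=(
            mp.OutcomeSpec("hypertension", 0.10, 1.0, ("I10",)),
            mp.OutcomeSpec("depression", 0.08, 1.0, ("F32.9",)),
        ),
        seed=11,
    )
    return mp.simulate_cohort(config, tree_edges=toy_edges,
                              background_rate=0.01,
                              background_codes=["E66.9", "M54.5", "N20.0"])


@pytest.fixture(scope="session")
def score(cohort, panel):
    s, _ = mp.weighted_score(cohort.dosages, panel)
    return s
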