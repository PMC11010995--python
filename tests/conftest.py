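"""Shared fixtures: the default synthetic study data and its doublet scores.

Session-scoped because doublet scoring trains a classifier (~30 s); every
test that needs the full-size default simulation shares one realization.
"""

import numpy as np
import pytest

from hybridcells.doublets import score_doublets
from hybridcells.simdata import (SimConfig, inject_doublets, make_programs,
                                 simulate_cells)


@pytest.fixture(scope="session")
def study_config():
    return SimConfig()  # the default study conditions, seed 0


@pytest.fixture(scope="session")
def study_data(study_config):
    """Default synthetic dataset: ~5,000 singlets + 1% hybrids + 5% doublets."""
    counts, truth = simulate_cells(study_config, make_programs(study_config))
    counts, truth = inject_doublets(counts, truth, study_config.doublet_rate,
                                    seed=study_config.seed)
    return counts, truth


@pytest.fixture(scope="session")
def study_scores(study_data, study_config):
    counts, _ = study_data
    return score_doublets(counts, seed=study_config.seed)


@pytest.fixture(scope="session")
def study_truth_masks(study_data):
    _, truth = study_data
    return {
        "doublet": (truth["true_label"] == "doublet").to_numpy(),
        "hybrid": (truth["true_label"] == "hybrid").to_numpy(),
        "singlet": (~truth["true_label"].isin(["doublet", "hybrid"])).to_numpy(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
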