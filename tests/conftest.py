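import numpy as np
import pandas as pd
import pytest

from regulonkit.quantio import CountMatrix, SampleSheet
from regulonkit.synthetic import (SimConfig, generate_chip_scores,
                                  generate_depletion_experiment,
                                  generate_meiosis_experiment,
                                  generate_stage_atlas)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def depletion_experiment(default_config):
    """Default depletion experiment, shared across tests (read-only)."""
    return generate_depletion_experiment(default_config)


@pytest.fixture(scope="session")
def meiosis_experiment(default_config):
    return generate_meiosis_experiment(default_config)


@pytest.fixture(scope="session")
def chip_and_atlas(default_config, depletion_experiment):
    _, _, _, truth = depletion_experiment
    truth = truth.copy()
    chip = generate_chip_scores(truth, default_config)
    atlas = generate_stage_atlas(truth, default_config)
    return chip, atlas, truth


@pytest.fixture(scope="session")
def planted():
    """Small experiment with promoter regions and planted URS1 cores."""
    from regulonkit.synthetic import generate_promoters

    cfg = SimConfig(seed=4, n_genes=60, n_direct_targets=20, n_confounded=5,
                    n_slow=5, motif_plant_fraction=0.8)
    _, _, _, truth = generate_depletion_experiment(cfg)
    regions = generate_promoters(truth, cfg)
    return cfg, truth, regions


@pytest.fixture()
def small_counts():
    """Tiny hand-checkable count matrix with a matching sample sheet."""
    genes = [f"g{i}" for i in range(6)]
    values = pd.DataFrame(
        {
            "control_0_1": [10, 90, 5, 0, 40, 7],
            "control_0_2": [12, 80, 6, 0, 38, 9],
            "depletion_0_1": [11, 85, 21, 0, 41, 8],
            "depletion_0_2": [9, 95, 19, 0, 39, 6],
        },
        index=genes,
    )
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": list(values.columns),
        "condition": ["control", "control", "depletion", "depletion"],
        "timepoint": [0, 0, 0, 0],
        "replicate": [1, 2, 1, 2],
    }))
    return CountMatrix(values), sheet
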