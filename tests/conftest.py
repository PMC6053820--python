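import numpy as np
import pandas as pd
import pytest

import ratiopanel as rp


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured study: 3 groups, 2 planted pairs."""
    return rp.SimulationConfig(
        n_species=40,
        n_per_group={"LAC": 18, "BENIGN": 14, "CONTROL": 14},
        n_per_group_validation={"LAC": 14, "BENIGN": 10, "CONTROL": 14},
        planted_pairs=(
            rp.PlantedPair(0, 1, 2.0, ("LAC", "BENIGN")),
            rp.PlantedPair(2, 3, 2.5, ("LAC",)),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return rp.simulate_study(small_config)


@pytest.fixture()
def count_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "species_id\tpool_1\tpool_2\n"
        "hsa-miR-22-3p\t60\t10\n"
        "hsa-miR-378a-3p\t40\t55\n"
    )
    return path


@pytest.fixture()
def ct_triplicate_tsv(tmp_path):
    path = tmp_path / "ct.tsv"
    path.write_text(
        "species_id\ts1_r1\ts1_r2\ts1_r3\n"
        "hsa-miR-22-3p\t28.0\t28.2\t28.4\n"
        "hsa-miR-378a-3p\t30.0\t30.1\t30.2\n"
    )
    return path
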