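import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cnvwing.config import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A small but fully populated synthetic screen: 17 lines, all assays."""
    return SimulationConfig(
        seed=7,
        n_wings_per_line=10,
        class_sizes={
            "no_phenotype": 5, "mild": 4, "moderate": 3, "severe": 3, "lethal": 2,
        },
        measurement_effects={"line_000": 0.5, "line_001": 1.0, "line_002": 1.3},
        eye_fc_effects={"line_000": 2.5, "line_001": 1.0, "line_002": 1.3},
        cell_rate_ratios={"line_000": 3.0, "line_001": 1.0},
        n_genes=40,
        n_tissues=6,
        preferential_fraction=0.25,
    )


@pytest.fixture
def screen_config() -> SimulationConfig:
    """Screen-scale composition (136 lines) for recovery tests."""
    return SimulationConfig(seed=11)
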