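import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from cytoscout.config import DistributionSpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def desk_config():
    """Small-geometry config with a point-mass WBC law for exact arithmetic."""
    return SimulationConfig(
        frames_per_slide=4,
        common_cells_per_frame=8,
        wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}),
        seed=0,
    )


@pytest.fixture
def render_config():
    """Config for rendering tests: few frames, high rare rates so the tiny
    rendered blood volume still contains events."""
    base = SimulationConfig()
    return SimulationConfig(
        frames_per_slide=6,
        common_cells_per_frame=8,
        wbc_per_ml_law=DistributionSpec("point", {"value": 6.0e6}),
        rare_rates={cat: rate * 4000 for cat, rate in base.rare_rates.items()},
        seed=0,
    )
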