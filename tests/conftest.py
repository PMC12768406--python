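import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ovisound import (
    GradientSimConfig,
    TrajectorySimConfig,
    TwoChoiceSimConfig,
    simulate_gradient,
    simulate_tracks,
    simulate_two_choice,
)


@pytest.fixture(scope="session")
def nights_default():
    return simulate_two_choice(TwoChoiceSimConfig(seed=11))


@pytest.fixture(scope="session")
def eggs_default():
    return simulate_gradient(GradientSimConfig(seed=12))


@pytest.fixture(scope="session")
def tracks_default():
    return simulate_tracks(TrajectorySimConfig(seed=13))


@pytest.fixture()
def eggs_frame():
    """Tiny hand-written gradient table."""
    return pd.DataFrame(
        {
            "night_index": [1, 1, 2, 2, 3],
            "female_id": ["f1", "f2", "f1", "f2", "f1"],
            "cluster_id": ["c1", "c2", "c3", "c4", "c5"],
            "position_cm": [-70.0, -30.0, 0.0, 10.0, -65.0],
            "n_eggs": [10, 2, 5, 1, 3],
        }
    )
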