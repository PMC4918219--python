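import numpy as np
import pytest

from swimodel import ModelParams
from swimodel.stimuli import SIZE_PAIRS, VOLUMES_CM3
from swimodel.model import visual_log_volume_mean


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def pair_vstars(default_params) -> dict[str, float]:
    """Canonical visual means for the six cube pairs."""
    return {
        f"{a}:{b}": visual_log_volume_mean(VOLUMES_CM3[a], VOLUMES_CM3[b], default_params)
        for a, b in SIZE_PAIRS
    }


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
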