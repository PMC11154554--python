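import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mhtcnn import ModelConfig, ScenarioConfig, SequenceMHT, generate_battery


@pytest.fixture(scope="session")
def small_battery():
    """A small, strongly separated battery shared by pipeline tests."""
    return generate_battery(ScenarioConfig(m=400, m0_frac=0.9, n=10,
                                           mu_alt=4.0, seed=11))


@pytest.fixture(scope="session")
def small_trained(small_battery):
    """A quickly trained classifier on the small battery (shared, read-only)."""
    config = ModelConfig(epochs=12, crop_length=256, crops_per_epoch=24,
                         batch_size=8, seed=5)
    return SequenceMHT.from_battery(small_battery, config=config).fit()
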