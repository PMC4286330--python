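import numpy as np
import pandas as pd
import pytest

from pettcp.model import TumorRecurrenceModel
from pettcp.simulate import GeneratorConfig
from pettcp.surrogates import SUVVolume


@pytest.fixture
def toy_cohort():
    """Four patients straddling the sigmoid: two responders, two nonresponders."""
    return pd.DataFrame(
        {
            "patient_id": ["A", "B", "C", "D"],
            "mean_ratio": [0.3, 0.4, 0.6, 0.8],
            "R": [0, 0, 1, 1],
        }
    )


@pytest.fixture
def toy_model(toy_cohort):
    return TumorRecurrenceModel.from_cohort_table(toy_cohort)


@pytest.fixture
def small_config():
    """A small, fast cohort configuration for rendering tests."""
    return GeneratorConfig(
        n_patients=12,
        n_responders=7,
        tumor_voxel_range=(30, 80),
        grid_shape=(16, 16, 16),
        seed=42,
    )


@pytest.fixture
def volume_pair():
    """A 3x2x2 registered pair with a 3-voxel tumor (pre SUV 4, 4, 8)."""
    pre = np.full((3, 2, 2), 1.0)
    post = np.full((3, 2, 2), 0.5)
    pre[0, 0, 0], pre[1, 0, 0], pre[2, 0, 0] = 4.0, 4.0, 8.0
    post[0, 0, 0], post[1, 0, 0], post[2, 0, 0] = 2.0, 1.0, 2.0
    return SUVVolume(pre), SUVVolume(post)
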