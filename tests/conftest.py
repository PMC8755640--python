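import numpy as np
import pytest

from slesa import BENIGN, MALIGNANT, ClassSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 ROIs (10/10), 32 px, well-separated textures: fast shared fixture."""
    cfg = SyntheticConfig(
        side_px=32,
        class_specs={
            BENIGN: ClassSpec(texture_frequency=3.0),
            MALIGNANT: ClassSpec(texture_frequency=11.0),
        },
        noise_sigma=0.05,
        n_per_class=10,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def study_dataset():
    """The reference study conditions: 36 benign + 37 malignant 64 px ROIs,
    class texture frequencies 4 vs 14 cycles/ROI, noise sigma 0.05."""
    cfg = SyntheticConfig(
        side_px=64,
        noise_sigma=0.05,
        n_per_class={BENIGN: 36, MALIGNANT: 37},
        seed=1,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
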