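import numpy as np
import pytest

from plaqueangle import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_lesion_config(**overrides) -> phantom.PhantomConfig:
    """A 40-frame phantom with a mixed lesion and a calcified lesion,
    matching the study geometry (0.30 mm frame increments, lumen contrast
    above 350 HU, lipid below it, calcium well above)."""
    defaults = dict(
        n_frames=40,
        image_size=128,
        noise_sd_hu=10.0,
        lesion_specs=(
            phantom.LesionSpec(
                (5, 15),
                [("lipid", 20.0, 110.0, 0.9), ("calcified", 200.0, 290.0, 0.95)],
                plaque_burden=0.6,
            ),
            phantom.LesionSpec(
                (22, 34),
                [("calcified", 300.0, 40.0, 0.9)],  # wraps through 0 degrees
                plaque_burden=0.5,
            ),
        ),
        seed=7,
    )
    defaults.update(overrides)
    return phantom.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def lesioned_phantom():
    """Generated once per session: (stack, ground truth, lesion table)."""
    return phantom.generate_stack(two_lesion_config())


@pytest.fixture
def clean_phantom():
    """Noise-free, jitter-free phantom for exact-value checks."""
    return phantom.generate_stack(two_lesion_config(noise_sd_hu=0.0, seed=3))
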