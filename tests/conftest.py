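import numpy as np
import pytest

from nirtex import (NoiseModel, StudyDesign, default_grid, generate_study,
                    records_to_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """A small noisy study: 2 blocks x 2 bags x 6 berries, 101-point grid."""
    design = StudyDesign(n_blocks=2, n_bags_per_block=2, n_berries_per_bag=6, seed=7)
    spectra, records = generate_study(design, grid=default_grid(101))
    return spectra, records, design


@pytest.fixture(scope="session")
def tiny_refs(tiny_study):
    _, records, _ = tiny_study
    return records_to_frame(records)


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise model with gentle levels, for tests needing a clean-ish signal."""
    return NoiseModel(multiplicative_sd=0.01, additive_sd=0.005,
                      baseline_slope_sd=0.002, white_sd=0.001,
                      face_sd=0.005, block_offset_sd=0.0)
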