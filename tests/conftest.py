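import warnings

import numpy as np
import pytest

from cslim import normalize, phantom


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # n < p LDA folds legitimately warn about the singular pooled covariance
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="singular pooled covariance")
        yield


@pytest.fixture(scope="session")
def small_truth() -> phantom.GroundTruth:
    """Small deterministic phantom shared by read-only tests."""
    spec = phantom.PhantomSpec(
        seed=42, shape=(256, 256), n_glands=2, gland_radius_um=(12.0, 18.0),
        n_fibers=10, background_noise_sd_rad=0.01,
    )
    return phantom.make_phase_phantom(spec)


@pytest.fixture(scope="session")
def small_zmap(small_truth) -> normalize.ZMap:
    return normalize.z_normalize(small_truth.phase, small_truth.tissue_mask)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
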