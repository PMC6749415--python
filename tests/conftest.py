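import numpy as np
import pytest

from metabopipe.synthetic import make_dataset


@pytest.fixture(scope="session")
def exact_noiseless():
    """Small exact-structure dataset with no noise or baseline (R=3)."""
    return make_dataset(
        n_samples=10,
        n_rt=80,
        n_mz=40,
        R=3,
        mode="exact_parafac2",
        shift_max=3,
        noise_sd=0.0,
        effect_log2fc=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def shifted_dataset():
    """Shifted-Gaussian dataset with mild noise, exercises COW.

    Concentration variability is kept low so TIC differences between
    samples are dominated by the retention shifts the warping must fix.
    """
    return make_dataset(
        n_samples=12,
        n_rt=200,
        n_mz=40,
        R=6,
        mode="shifted_gaussian",
        shift_max=3,
        snr_db=30.0,
        cv_within=0.05,
        effect_log2fc=0.0,
        seed=21,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
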