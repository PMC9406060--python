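import os

# single-threaded BLAS: bitwise-reproducible training trajectories
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from ventralenc.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def h0_dataset():
    """Tiny noiseless V1-only dataset (side 32, 200/40 split)."""
    return generate_dataset(SyntheticConfig.h0(), seed=7)


@pytest.fixture(scope="session")
def tiny_two_roi_dataset():
    """Small V1+V2 dataset for pipeline plumbing tests (side 32)."""
    cfg = SyntheticConfig(
        name="tiny2",
        side=32,
        n_train=120,
        n_val=40,
        roi_sizes={"V1": 40, "V2": 30},
        snr={"V1": np.inf, "V2": 3.0},
    )
    return generate_dataset(cfg, seed=3)
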