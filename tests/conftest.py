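from dataclasses import replace

import numpy as np
import pytest

from splitgap import FeatureTable, GeneratorConfig, calibrate_shift, generate_dataset


@pytest.fixture(scope="session")
def separable_table() -> FeatureTable:
    """Two tight, far-apart point clouds: any sensible fit scores AUC 1."""
    rng = np.random.default_rng(11)
    x0 = rng.normal(0.0, 0.05, size=(25, 6))
    x1 = rng.normal(5.0, 0.05, size=(15, 6))
    return FeatureTable(
        values=np.vstack([x0, x1]),
        labels=np.concatenate([np.zeros(25, int), np.ones(15, int)]),
    )


@pytest.fixture(scope="session")
def signal_table() -> FeatureTable:
    """Moderate-difficulty synthetic table used across estimator tests."""
    cfg = GeneratorConfig(
        n_class0=60, n_class1=40, p_total=40, m_informative=5,
        n_redundant=10, delta=0.7, seed=5,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noise_config() -> GeneratorConfig:
    """No-signal generator (delta = 0): labels independent of features."""
    return GeneratorConfig(
        n_class0=40, n_class1=30, p_total=30, m_informative=3,
        n_redundant=5, delta=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def difficult_small_config() -> GeneratorConfig:
    """Small difficult-task generator (oracle AUC 0.78) for quick trials."""
    skeleton = GeneratorConfig(
        n_class0=70, n_class1=50, p_total=60, m_informative=5,
        n_redundant=10, seed=9,
    )
    return replace(skeleton, delta=calibrate_shift(0.78, skeleton))
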