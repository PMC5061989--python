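import numpy as np
import pytest

import fuzzybci as fb


@pytest.fixture(scope="session")
def small_dataset():
    """Six-class synthetic dataset at the default 10 s/class protocol."""
    return fb.generate_dataset(1, fb.default_specs(), duration_s=10.0, seed=42)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """896-feature matrix for the small dataset (54 windows)."""
    return fb.extract_features(small_dataset)


@pytest.fixture(scope="session")
def small_selected(small_features):
    """Top-100 info-gain features of the small dataset."""
    ranking = fb.info_gain_rank(small_features)
    return fb.select_top_k(small_features, ranking, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_recording():
    """Two-channel ramp recording, 512 samples at 128 Hz."""
    t = np.arange(512, dtype=float)
    data = np.column_stack([t, np.sin(2 * np.pi * 8 * t / 128.0)])
    return fb.Recording(("ch1", "ch2"), data, sample_rate=128.0, label="forward")


def make_model(m, r, n, seed=0, width_range=(0.3, 1.0)):
    """Random small FNN with sane widths, for forward/gradient tests."""
    g = np.random.default_rng(seed)
    return fb.FNNModel(
        fb.AntecedentSet(g.normal(0, 1, (m, r)),
                         g.uniform(*width_range, (m, r))),
        fb.ConsequentSet(g.normal(0, 1, (m, r)), g.normal(0, 1, r)),
        fb.MixingWeights(g.normal(0, 1, (r, n))),
    )
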