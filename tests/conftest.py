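import numpy as np
import pytest

from caehar import synth, tffe


@pytest.fixture(scope="session")
def tiny_har():
    """Small but complete synthetic dataset: 19 classes x 2 subjects x 3 segs."""
    cfg = synth.HARGenConfig(n_subjects=2, segments_per_pair=3, seed=123)
    return synth.make_har_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_har):
    segments, labels = tiny_har
    return tffe.extract_matrix(segments), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture()
def one_segment():
    cfg = synth.HARGenConfig(n_activities=1, n_subjects=1,
                             segments_per_pair=1, seed=5)
    segments, _ = synth.make_har_dataset(cfg)
    return segments[0]
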