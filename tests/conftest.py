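import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def assert_valid_stream():
    """Validator applied to every stream a test emits."""

    def _check(stream):
        stream.validate()
        assert len(stream.times) == len(stream.sources)
        if len(stream):
            assert stream.times[0] >= 0
            assert np.all(np.diff(stream.times) >= 0)
            assert stream.sources.min() >= 0
            assert stream.sources.max() < stream.n_sources
            assert stream.times[-1] <= stream.duration + 1e-12

    return _check
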