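import numpy as np
import pytest

from zwstrata import strata


def make_windows(values, window=100_000, aligned_bp=100_000):
    return [
        strata.SimilarityWindow(i * window, (i + 1) * window, float(v), aligned_bp)
        for i, v in enumerate(values)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
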