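import numpy as np
import pytest

from dcef.fusion_core import ClassifierWeights, FeatureBatch, LabelBatch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, n=None, d=None, c=2):
    """A random (features, weights, labels) triple for gradient/loss tests."""
    n = n or int(rng.integers(1, 9))
    d = d or int(rng.integers(1, 6))
    fb = FeatureBatch(rng.standard_normal((n, d)))
    cw = ClassifierWeights(rng.standard_normal((d, c)))
    lab = LabelBatch(rng.integers(0, c, n))
    return fb, cw, lab
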