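import numpy as np
import pytest

from codebrain.glm import BinaryActivationMap
from codebrain.surface_synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synth():
    """A scaled-down synthetic study used by unit tests."""
    return SynthConfig(n_subjects=3, n_vertices_per_hemi=400, seed=11)


def make_binary_map(values, hemispheres=None, **kw):
    values = np.asarray(values)
    if hemispheres is None:
        half = values.size // 2
        hemispheres = np.array(["L"] * half + ["R"] * (values.size - half))
    return BinaryActivationMap(values=values, hemispheres=np.asarray(hemispheres), **kw)
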