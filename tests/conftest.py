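import numpy as np
import pytest

from octamorph.synthetic import FazShapeParams, TreeParams, generate_vessel_tree


@pytest.fixture(scope="session")
def tree_fixture():
    """One default synthetic angiogram with ground truth (seed 7)."""
    params = TreeParams(seed=7, faz=FazShapeParams(seed=7))
    image, mask, gt = generate_vessel_tree(params)
    return params, image, mask, gt


@pytest.fixture(scope="session")
def tree_suite():
    """A small bank of synthetic trees for property sweeps."""
    out = []
    for seed in range(6):
        params = TreeParams(seed=seed, faz=FazShapeParams(seed=seed))
        out.append((params,) + generate_vessel_tree(params))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
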