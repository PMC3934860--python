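import numpy as np
import pytest

from allogrow import read_newick, simulate_tree


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); — equal root-to-tip distance 2."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Ultrametric star: diagonal Brownian covariance."""
    return read_newick("(A:1,B:1,C:1);")


@pytest.fixture(params=[4, 5, 6])
def small_yule_tree(request):
    return simulate_tree(request.param, seed=40 + request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
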