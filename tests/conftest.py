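import numpy as np
import pytest

import decranges as dr


@pytest.fixture
def three_area_space():
    return dr.enumerate_ranges(3, 2)


@pytest.fixture
def five_tip_tree():
    return dr.read_tree("(((a:1,b:1):0.5,c:1.5):0.5,(d:1,e:1):1);")


@pytest.fixture
def cherry_tree():
    return dr.read_tree("(a:1,b:1);")


def random_single_area_tips(labels, n_areas, rng):
    return {l: dr.RangeState((int(rng.integers(n_areas)),)) for l in labels}


@pytest.fixture
def rng():
    return np.random.default_rng(20230729)
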