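import math

import numpy as np
import pytest

from arbornet import Arbor, GrowthParams, grow_arbor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_ray():
    """Deterministic no-branching arbor: one ray from the origin along +x."""
    params = GrowthParams(branch_rate=0.0, max_deviation=math.pi, t_max=3.0)
    return Arbor(
        start=np.array([[0.0, 0.0]]),
        direction=np.array([0.0]),
        birth_time=np.array([0.0]),
        end_time=np.array([3.0]),
        parent=np.array([-1]),
        params=params,
    )


def make_arbor(seed: int, branch_rate=1.5, max_deviation=math.pi, t_max=1.0, root=(0.0, 0.0)):
    params = GrowthParams(branch_rate, max_deviation, t_max)
    return grow_arbor(root, params, np.random.default_rng(seed))
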