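import math

import numpy as np
import pytest
from hypothesis import settings

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def naive_rao_u(raw_angles):
    """Independent brute-force Rao U: selection-sort the wrapped angles and
    accumulate the spacing deviations with a plain Python loop."""
    two_pi = 2.0 * math.pi
    vals = [float(v) % two_pi for v in raw_angles]
    out = []
    while vals:  # selection sort, no library sorting
        m = min(range(len(vals)), key=lambda i: vals[i])
        out.append(vals.pop(m))
    n = len(out)
    arcs = [out[i + 1] - out[i] for i in range(n - 1)]
    arcs.append(two_pi - out[-1] + out[0])
    return 0.5 * sum(abs(a - two_pi / n) for a in arcs)
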