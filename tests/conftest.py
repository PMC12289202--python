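import numpy as np
import pytest

from coevodyn import BASELINE, find_fixed_points


@pytest.fixture(scope="session")
def baseline():
    return BASELINE


@pytest.fixture(scope="session")
def baseline_fps(baseline):
    """All baseline fixed points, classified, sorted by beta*."""
    return find_fixed_points(baseline)


@pytest.fixture(scope="session")
def attractors(baseline_fps):
    """The two stable attractors keyed by interaction type."""
    out = {}
    for fp in baseline_fps:
        if fp.stability == "stable":
            key = "M" if fp.interaction_type == "mutualistic" else "A"
            out[key] = fp
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240923)
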