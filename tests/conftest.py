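import numpy as np
import pytest

from firstpassage import presets
from firstpassage.fpt import extract_fpt_events_ensemble
from firstpassage.landscapes import make_channel_landscape


@pytest.fixture(scope="session")
def four_well():
    """The packaged four-well, 3 kBT channel landscape."""
    return presets.COLLOID_FIG1.landscape()


@pytest.fixture(scope="session")
def colloid_small():
    """A small colloid ensemble shared by unit tests (events, landscape)."""
    p = presets.COLLOID_FIG1
    ls = p.landscape()
    trajs = p.simulate(seed=1234, n_trajectories=250)
    events, summary = extract_fpt_events_ensemble(trajs, ls)
    return {"events": events, "landscape": ls, "summary": summary,
            "trajectories": trajs[:20], "preset": p}


@pytest.fixture(scope="session")
def flat_channel():
    return make_channel_landscape(0, 0.0, 4.8)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
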