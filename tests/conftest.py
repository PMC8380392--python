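import numpy as np
import pytest

from vestcomp.core import PAWS, ForceFrame, PawState

#: default square stance: FL, FR, RL, RR (x antero-posterior, y lateral)
STANCE_XY = {
    "FL": (4.0, -2.0), "FR": (4.0, 2.0), "RL": (-4.0, -2.5), "RR": (-4.0, 2.5),
}


def make_frame(t, weights, xy=None, abdomen=0.0):
    """One ForceFrame from a {paw: force} mapping (positions default to STANCE_XY)."""
    xy = xy or STANCE_XY
    return ForceFrame(
        t=t,
        paws={p: PawState(xy[p][0], xy[p][1], float(weights[p])) for p in PAWS},
        abdomen_w=abdomen,
    )


def make_frames(times, weights_per_frame, xy=None, abdomen=None):
    """Frame sequence from per-frame {paw: force} mappings."""
    abdomen = abdomen if abdomen is not None else [0.0] * len(times)
    return [make_frame(t, w, xy=xy, abdomen=a)
            for t, w, a in zip(times, weights_per_frame, abdomen)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def steady_frames():
    """10 s of constant four-paw loading at 10 Hz."""
    times = np.arange(0, 10.0, 0.1)
    w = {p: 75.0 for p in PAWS}
    return make_frames(times, [w] * len(times))
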