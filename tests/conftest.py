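import numpy as np
import pytest

from dyadflow import synthdyad
from dyadflow.preprocess import Channel, ChannelGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def schedule():
    """Protocol-scale run: 180 s, 15 s alternating turns."""
    return synthdyad.generate_turn_schedule(180, 15, "A", "B")


@pytest.fixture
def small_geometry():
    """Six-channel montage over four ROIs (keeps generator tests fast)."""
    return ChannelGeometry(
        (
            Channel("c1", "L", "AG"),
            Channel("c2", "R", "AG"),
            Channel("c3", "L", "SMG"),
            Channel("c4", "R", "SMG"),
            Channel("c5", "L", "STG"),
            Channel("c6", "L", "OTC"),
        )
    )
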