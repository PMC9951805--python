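from datetime import datetime

import numpy as np
import pytest

from civetniche.core_io import DetectionEvent, DetectionTable
from civetniche.datasets import load_plnp_composition


@pytest.fixture(scope="session")
def plnp():
    """The packaged civet diet composition table."""
    return load_plnp_composition()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230221)


def make_events(minute_offsets, site="S01", species="sp", start=None):
    """Detection events at the given minute offsets from a fixed origin."""
    start = start or datetime(2021, 3, 1, 0, 0)
    from datetime import timedelta

    return DetectionTable(
        DetectionEvent(site, species, start + timedelta(minutes=float(m)))
        for m in minute_offsets
    )
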