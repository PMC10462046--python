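import numpy as np
import pytest
from hypothesis import settings

from scramblekit.trajectory_io import BoxVectors, Frame, SystemTopology

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def box():
    return BoxVectors(10.0, 10.0, 10.0)


@pytest.fixture
def bilayer_topology():
    """Four POPC lipids, one PO4 bead each."""
    n = 4
    return SystemTopology(
        names=np.array(["PO4"] * n),
        resnames=np.array(["POPC"] * n),
        resids=np.arange(1, n + 1),
    )


def make_frame(positions, time=0.0, box_lengths=(10.0, 10.0, 10.0)):
    return Frame(time=time, positions=np.asarray(positions, dtype=float),
                 box=BoxVectors(*box_lengths))


@pytest.fixture
def protein_topology():
    """Toy protein: 250 backbone beads, resids 1..250."""
    n = 250
    return SystemTopology(
        names=np.array(["BB"] * n),
        resnames=np.array(["ALA"] * n),
        resids=np.arange(1, n + 1),
    )
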