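import numpy as np
import pytest

from cpgnet import netsim, topology


@pytest.fixture(scope="session")
def dense_sim():
    """One short dense-topology simulation reused across tests.

    20 sources, in-degree 10, 8 receivers, 16 s — long enough for the
    0.2 Hz band-pass, short enough to keep the suite quick.
    """
    top = topology.build_fixed_indegree(20, 8, 10, seed=11)
    drive = netsim.DriveParams(r0=12.0, r1=10.0, f_hz=1.0, duration_s=16.0)
    vm, spikes = netsim.simulate(netsim.FIG2_CELL, netsim.FIG2_SYNAPSE, top,
                                 drive, seed=12)
    return vm, spikes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
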