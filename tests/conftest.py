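import numpy as np
import pytest

from condensim import SimParams, SystemState, Topology


@pytest.fixture
def tiny_params():
    return SimParams(n_chains=1, N=60, M=3, Cr=1, shell_D1=5.24)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_system(n_mon, n_cond, rng, box=4.0, n_chains=1,
                       with_springs=True, with_anchors=True):
    """Random particle soup in a box, a chain path over the monomers,
    and condensins anchored to random monomer pairs."""
    mon_pos = rng.uniform(-box, box, size=(n_mon, 3))
    cond_pos = rng.uniform(-box, box, size=(n_cond, 3))
    N = n_mon // n_chains
    state = SystemState(
        mon_pos=mon_pos,
        mon_vel=np.zeros_like(mon_pos),
        cond_pos=cond_pos,
        cond_vel=np.zeros_like(cond_pos),
        mon_chain=np.repeat(np.arange(n_chains, dtype=np.int64), N),
        cond_chain=(np.arange(n_cond, dtype=np.int64) * n_chains
                    // max(n_cond, 1)),
    )
    springs = np.zeros((0, 2), dtype=np.int64)
    if with_springs:
        topo = Topology.linear_chains(n_chains, N)
        springs = topo.springs
    anchors = np.zeros((0, 2), dtype=np.int64)
    if with_anchors and n_cond:
        anchors = np.sort(
            rng.choice(n_mon, size=(n_cond, 2), replace=True), axis=1
        ).astype(np.int64)
    return state, Topology(springs=springs, anchors=anchors)
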