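import numpy as np
import pytest

from wedana.io import Endpoint, SegmentRecord, open_we_file, write_we_file
from wedana.synthetic import DiscreteChain, DoubleWell, WEConfig, run_we


@pytest.fixture(scope="session")
def chain_config():
    """Recycling WE over a 6-state reflected walk, target at the top state."""
    return WEConfig(
        bin_edges=np.arange(-0.5, 6.5, 1.0),
        dynamics=DiscreteChain(n_states=6, hop_prob=0.5),
        n_iterations=40,
        target_count=4,
        frames_per_tau=5,
        tau_seconds=100e-12,
        target_condition=4.5,
        basis_states=[(0.0, 0.6), (1.0, 0.4)],
        seed=1,
    )


@pytest.fixture(scope="session")
def chain_run(tmp_path_factory, chain_config):
    d = tmp_path_factory.mktemp("chain_run")
    west, kinetics = run_we(chain_config, d / "west.h5", d / "kinetics.h5")
    return west, kinetics


@pytest.fixture()
def chain_handle(chain_run):
    with open_we_file(chain_run[0]) as h:
        yield h


@pytest.fixture(scope="session")
def well_run(tmp_path_factory):
    """Equilibrium (non-recycling) double-well run with two basis states."""
    cfg = WEConfig(
        bin_edges=np.linspace(-2.0, 2.0, 9),
        dynamics=DoubleWell(beta=2.0, diffusion=0.5, dt=0.05),
        n_iterations=20,
        target_count=4,
        frames_per_tau=4,
        tau_seconds=100e-12,
        recycle=False,
        basis_states=[(-1.0, 0.5), (1.0, 0.5)],
        seed=7,
    )
    d = tmp_path_factory.mktemp("well_run")
    west, kinetics = run_we(cfg, d / "west.h5", d / "kinetics.h5")
    return west, kinetics


@pytest.fixture()
def well_handle(well_run):
    with open_we_file(well_run[0]) as h:
        yield h


def build_lineage_file(path):
    """Hand-built 3-iteration tree with a known chain (1,1)->(2,0)->(3,2).

    Two basis states; segment (3,2) is marked recycled.  pcoord is continuous
    across parent links (2 frames per segment) and 'auxdata/rog' mirrors it.
    """
    C = Endpoint.CONTINUES
    # iteration 1: seg0 from basis 0, seg1 from basis 1
    rec1 = [
        SegmentRecord(1, 0, 0.5, -1, C),
        SegmentRecord(1, 1, 0.5, -2, C),
    ]
    pc1 = np.array([[0.0, 1.0], [5.0, 6.0]])  # final frames: 1.0, 6.0
    # iteration 2: seg0 continues seg (1,1); seg1 continues seg (1,0)
    rec2 = [
        SegmentRecord(2, 0, 0.5, 1, C),
        SegmentRecord(2, 1, 0.5, 0, C),
    ]
    pc2 = np.array([[6.0, 7.0], [1.0, 2.0]])
    # iteration 3: seg2 continues (2,0) and recycles; seg0,seg1 continue (2,1)
    rec3 = [
        SegmentRecord(3, 0, 0.25, 1, C),
        SegmentRecord(3, 1, 0.25, 1, C),
        SegmentRecord(3, 2, 0.5, 0, Endpoint.RECYCLED),
    ]
    pc3 = np.array([[2.0, 3.0], [2.0, 2.5], [7.0, 8.0]])
    iterations = [
        (rec1, {"pcoord": pc1, "auxdata/rog": pc1 * 2.0}),
        (rec2, {"pcoord": pc2, "auxdata/rog": pc2 * 2.0}),
        (rec3, {"pcoord": pc3, "auxdata/rog": pc3 * 2.0}),
    ]
    return write_we_file(path, iterations)


@pytest.fixture()
def lineage_file(tmp_path):
    return build_lineage_file(tmp_path / "lineage.h5")


@pytest.fixture()
def lineage_handle(lineage_file):
    with open_we_file(lineage_file) as h:
        yield h
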