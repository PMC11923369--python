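import numpy as np
import pytest
from hypothesis import settings

from pincermd import (PincerSpec, Topology, Trajectory, domain_map_for,
                      generate_pincer_trajectory)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_spec():
    """Desk-scale pincer system: 4 domains x 10 residues, 200 frames."""
    return PincerSpec(
        n_domains=4, residues_per_domain=10, jaw_pair=("PAZ", "L2"),
        closed_distance=30.0, amplitude=10.0, period=100, phase=0,
        fluctuation_sigma=0.3, n_frames=200, seed=7)


@pytest.fixture
def small_traj(small_spec):
    return generate_pincer_trajectory(small_spec)


@pytest.fixture
def small_map(small_spec):
    return domain_map_for(small_spec)


def make_topology(n_atoms, resids=None, names=None, resnames=None,
                  elements=None, masses=None):
    """Minimal hand-built topology for constructed-geometry tests."""
    return Topology(
        serials=np.arange(1, n_atoms + 1),
        names=tuple(names) if names else ("CA",) * n_atoms,
        resids=np.asarray(resids if resids is not None
                          else np.arange(1, n_atoms + 1)),
        resnames=tuple(resnames) if resnames else ("GLY",) * n_atoms,
        masses=np.asarray(masses if masses is not None else np.ones(n_atoms),
                          dtype=float),
        elements=tuple(elements) if elements else ("C",) * n_atoms,
    )


def make_trajectory(coords, **topology_kwargs):
    coords = np.asarray(coords, dtype=float)
    top = make_topology(coords.shape[1], **topology_kwargs)
    return Trajectory(topology=top, coords=coords, stride_ps=10.0)
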