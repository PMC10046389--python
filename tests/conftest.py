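import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def helix_tails():
    """Standard rigid-helix-with-disordered-tails system plus ground truth."""
    from pbtraj import make_helix_with_tails

    return make_helix_with_tails(n_frames=300, seed=11)


@pytest.fixture(scope="session")
def probe_system():
    """Three-probe mixture system: pure helix, helix/strand 50:50, uniform."""
    from pbtraj import sample_system

    mixtures = standard_probe_mixtures()
    traj, gt = sample_system(30, mixtures, n_frames=2000, jitter_deg=5.0,
                             seed=17)
    return traj, gt, mixtures


def standard_probe_mixtures():
    pure_m = np.zeros(16)
    pure_m[12] = 1.0
    md = np.zeros(16)
    md[12] = 0.5
    md[3] = 0.5
    return {358: pure_m, 364: md, 370: np.full(16, 1 / 16)}


@pytest.fixture()
def tiny_traj():
    """A hand-built 2-residue, 2-frame system for exact geometry tests."""
    from pbtraj.trajectory import AtomRecord, ResidueRecord, Trajectory

    residues = [
        ResidueRecord("A", 1, "GLY", [AtomRecord("CA", "C")]),
        ResidueRecord("A", 2, "GLY", [AtomRecord("CA", "C")]),
    ]
    coords = np.array([
        [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
        [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
    ])
    return Trajectory(residues, coords, np.array([0.0, 100.0]), "tiny")
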