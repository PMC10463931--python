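import numpy as np
import pytest

from ddpd import fixtures


@pytest.fixture
def peptide_topology():
    """Three peptide-backbone residues: 15 atoms, 3 residues."""
    return fixtures.synth_topology(3)


@pytest.fixture
def small_trajectory():
    topo = fixtures.synth_topology(10)
    profile = fixtures.FluctuationProfile(
        sigma=np.full(10, 0.05), n_frames=300, seed=42
    )
    return fixtures.synth_trajectory(topo, profile)


@pytest.fixture
def identity_msa():
    """Two identical ungapped 10-residue rows."""
    return fixtures.synth_msa({"A": "ACDEFGHIKL", "B": "ACDEFGHIKL"})
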