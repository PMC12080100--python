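import numpy as np
import pytest

from gsnet.synthetic import SynthSpec, assign_charges, generate_structure


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed to +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def helix20():
    """20-residue jittered helix with charges; reused across read-only tests."""
    s = generate_structure(SynthSpec(n_residues=20, conformation="helix", jitter_sd=0.3, seed=7))
    return assign_charges(s)


@pytest.fixture(scope="session")
def coil12():
    s = generate_structure(SynthSpec(n_residues=12, conformation="coil", jitter_sd=0.2, seed=11))
    return assign_charges(s)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
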