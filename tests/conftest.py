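import numpy as np
import pytest

from wepath.structures import Conformation
from wepath.toy_system import HingeSpec, make_hinge_endpoints


@pytest.fixture(scope="session")
def hinge_endpoints():
    """Default open/closed hinge endpoints (N = 21, no jitter)."""
    return make_hinge_endpoints(HingeSpec())


@pytest.fixture(scope="session")
def small_hinge_endpoints():
    """Small hinge (N = 11) for quicker dynamics-heavy tests."""
    return make_hinge_endpoints(HingeSpec(n_per_arm=5))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def hinge_we_run(small_hinge_endpoints):
    """A short real WE run on the small hinge (shared by analysis tests)."""
    from wepath.adaptive_anm import generate_pathway
    from wepath.pcoord import Embedding2D, build_polyline, embed, progress
    from wepath.structures import rmsd
    from wepath.toy_system import make_brownian_propagator, make_double_basin
    from wepath.we_engine import MabBinMapper, WeRunConfig, run_we

    a, b = small_hinge_endpoints
    potential = make_double_basin(a, b)
    embedding = Embedding2D(a, b)
    polyline = build_polyline(generate_pathway(a, b), embedding)
    propagator = make_brownian_propagator(potential, n_steps=20, temperature=2.0)
    config = WeRunConfig(n_iterations=8, tau=20.0, seed=7)
    return run_we(
        propagator, a,
        lambda c: progress(embed(c, embedding), polyline).value,
        MabBinMapper(), config,
        target_state=lambda c: rmsd(c, b) < 2.0,
    )


def random_conformation(rng, n=8, name="rand"):
    """A random, generically non-degenerate conformation."""
    labels = tuple(f"A:GLY:{i + 1}" for i in range(n))
    return Conformation(labels, 10.0 * rng.standard_normal((n, 3)), name=name)


def random_rotation(rng):
    """Uniform random proper rotation via QR with sign fix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
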