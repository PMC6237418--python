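import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from swarmdmd.features import SnapshotSequence
from swarmdmd.schooling import regime_params, simulate
from swarmdmd.synthetic import koopman_oscillator_fixture, linear_fixture


def rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@pytest.fixture(scope="session")
def linear_seq():
    """Noise-free 4-D linear system with known spectrum."""
    A = np.block(
        [
            [0.9 * rotation(np.pi / 8), np.zeros((2, 2))],
            [np.zeros((2, 2)), np.diag([0.8, 0.5])],
        ]
    )
    seq, eigs = linear_fixture(A, tau=200, noise_sd=0.0, seed=0, dt=0.1)
    return seq, eigs


@pytest.fixture(scope="session")
def oscillator_seq():
    return koopman_oscillator_fixture(lam=0.95, mu=0.5, c=1.0, tau=100)


@pytest.fixture(scope="session")
def regime_trajectories():
    """One analysis-window trajectory per named regime (5 seeds each).

    Session-scoped: the 40 s simulations dominate the suite's runtime and
    are shared between the regime-separation, spectrum and dispersion tests.
    """
    out = {}
    for regime in ("swarm", "torus", "parallel"):
        windows = []
        for seed in range(5):
            p = regime_params(regime, seed=seed)
            tr = simulate(p)
            windows.append(tr.window(p.analysis_start, p.analysis_start + 10.0))
        out[regime] = windows
    return out


@pytest.fixture(scope="session")
def torus_window(regime_trajectories):
    return regime_trajectories["torus"][0]
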