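import numpy as np
import pytest

from torsionswarm.conformation import TorsionChain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_chain(rng, L: int) -> TorsionChain:
    """Random valid torsion chain with angles in (-179, 180]."""
    phi = np.concatenate([[np.nan], rng.uniform(-179.0, 180.0, L - 1)])
    psi = np.concatenate([rng.uniform(-179.0, 180.0, L - 1), [np.nan]])
    omega = np.concatenate([rng.uniform(-179.0, 180.0, L - 1), [np.nan]])
    return TorsionChain(phi, psi, omega)


@pytest.fixture
def helix_chain() -> TorsionChain:
    return TorsionChain.uniform(12, -57.0, -47.0)


def max_angle_error(a: TorsionChain, b: TorsionChain) -> float:
    """Largest circular difference between two chains' defined angles (deg)."""
    errs = []
    for x, y in ((a.phi, b.phi), (a.psi, b.psi), (a.omega, b.omega)):
        d = np.abs(((x - y) + 180.0) % 360.0 - 180.0)
        errs.append(np.nanmax(d))
    return float(max(errs))
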