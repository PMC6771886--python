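import numpy as np
import pytest

from cestpvc.forward import Pool, SaturationProtocol
from cestpvc.inference import PriorSpec
from cestpvc.params import default_protocol, default_tissue_pools
from cestpvc.pvc import CompartmentModel


@pytest.fixture(scope="session")
def protocol() -> SaturationProtocol:
    return default_protocol()


@pytest.fixture(scope="session")
def tissue_pools() -> list[Pool]:
    return default_tissue_pools()


@pytest.fixture(scope="session")
def compartments() -> CompartmentModel:
    return CompartmentModel()


@pytest.fixture(scope="session")
def priors() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def offsets(protocol) -> np.ndarray:
    return np.asarray(protocol.offsets)


def random_pool_system(
    rng: np.random.Generator,
    n_pools: int,
    solute_t2: tuple[float, float] = (10**-4.5, 10**-1.5),
) -> list[Pool]:
    """A physically plausible random 2-4 pool system for oracle comparisons.

    ``solute_t2`` bounds the solute transverse relaxation times; tests that
    check against a time-stepping ODE integrator pass a floor of ~1 ms, since
    semisolid-like 10 us T2 values make the equations too stiff for any
    adaptive integrator to traverse a 2 s saturation in reasonable time (the
    stiff regime is covered separately against the Pade matrix exponential).
    """
    pools = [
        Pool("water", m0=1.0, kex=0.0, t1=rng.uniform(0.8, 3.0), t2=rng.uniform(0.03, 0.5), dw=0.0)
    ]
    lo, hi = solute_t2
    for i in range(n_pools - 1):
        t1 = rng.uniform(0.5, 2.0)
        pools.append(
            Pool(
                f"solute{i}",
                m0=10 ** rng.uniform(-4, -1.5),
                kex=10 ** rng.uniform(0.5, 2.5),
                t1=t1,
                t2=min(10 ** rng.uniform(np.log10(lo), np.log10(hi)), t1),
                dw=rng.uniform(-4.0, 4.0),
            )
        )
    return pools
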