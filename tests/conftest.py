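import pytest

from cestmrf.physics import PoolParameters, TissueParameters
from cestmrf.schedule import generate_pseudorandom_schedule


@pytest.fixture(scope="session")
def larg_tissue():
    """L-arginine-like two-pool tissue (3-ppm amine pool, 50 mM-ish)."""
    return TissueParameters(
        water=PoolParameters(t1=2.5, t2=0.8),
        solute=PoolParameters(t1=1.0, t2=0.04, chemical_shift=3.0,
                              exchange_rate=400.0, volume_fraction=1.35e-3))


@pytest.fixture(scope="session")
def schedule30():
    """Full-length 30-entry CEST schedule."""
    return generate_pseudorandom_schedule(30, "cest_3ppm", seed=7)


@pytest.fixture(scope="session")
def schedule6():
    """Short schedule for cheap unit tests."""
    return generate_pseudorandom_schedule(6, "cest_3ppm", seed=3)
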