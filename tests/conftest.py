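import numpy as np
import pytest

from hippomicro.sandi import AcquisitionProtocol


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    """The 8-shell PGSE protocol used throughout (δ = 8 ms, Δ = 19 ms)."""
    return AcquisitionProtocol.default()


@pytest.fixture(scope="session")
def small_protocol() -> AcquisitionProtocol:
    """Same shells with few directions, for fast volumetric simulations."""
    base = AcquisitionProtocol.default()
    return AcquisitionProtocol(
        shells=base.shells,
        directions_per_shell=(6,) * len(base.shells),
        delta_small=base.delta_small,
        delta_big=base.delta_big,
        b0_count=3,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
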