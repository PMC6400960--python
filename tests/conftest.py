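import numpy as np
import pytest

from netflics import forward as fw
from netflics import phantoms as ph


@pytest.fixture(scope="session")
def axis():
    return fw.TemporalAxis()


@pytest.fixture(scope="session")
def irf(axis):
    return fw.gaussian_irf(axis)


@pytest.fixture(scope="session")
def bank():
    """Default acquisition bank: 512 sequency-ranked patterns of order 1024."""
    return fw.build_hadamard_bank()


@pytest.fixture(scope="session")
def bank_complete():
    """Complete order-1024 bank (square, exactly invertible)."""
    return fw.build_hadamard_bank(k=1024)


@pytest.fixture(scope="session")
def bank_toy():
    """8x8-frame bank (order 64), for fast solver oracle checks."""
    return fw.build_hadamard_bank(order=64, k=64)


@pytest.fixture(scope="session")
def scene():
    """One bright single-glyph scene with a single ground-truth lifetime."""
    return ph.make_scene([ph.make_glyph(1)], "3", rng_seed=42, scene_id="dev-0")


@pytest.fixture(scope="session")
def toy_axis():
    """Coarse 32-gate axis for cheap temporal tests (span 6.4 ns)."""
    return fw.TemporalAxis(n_gates=32, gate_width=0.2)
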