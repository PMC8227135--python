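import numpy as np
import pytest

import sonochamber as sc


@pytest.fixture(scope="session")
def registry():
    return sc.default_materials()


@pytest.fixture(scope="session")
def water(registry):
    return registry["water"]


@pytest.fixture(scope="session")
def glass(registry):
    return registry["glass"]


@pytest.fixture(scope="session")
def polystyrene(registry):
    return registry["polystyrene"]


@pytest.fixture(scope="session")
def air(registry):
    return registry["air"]


@pytest.fixture(scope="session")
def lossless(registry):
    """Registry with all attenuation switched off (energy-conservation tests)."""
    reg = sc.MaterialRegistry()
    for m in registry:
        reg.add(m.with_(alpha0_db_per_cm=0.0))
    return reg


def chamber_stack(reg, slide="glass", coverslip="glass",
                  gap=15e-6, slide_d=1.2e-3, cover_d=0.17e-3,
                  bath="water", sample="water", backing="air"):
    """The canonical bath | slide | sample | coverslip | backing stack."""
    return sc.LayerStack.from_sequence([
        (reg[bath], sc.HALF_SPACE),
        (reg[slide], slide_d),
        (reg[sample], gap),
        (reg[coverslip], cover_d),
        (reg[backing], sc.HALF_SPACE),
    ])


@pytest.fixture()
def default_stack(registry):
    return chamber_stack(registry)


@pytest.fixture()
def lossless_stack(lossless):
    return chamber_stack(lossless)
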