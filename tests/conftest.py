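import itertools

import pytest
from hypothesis import HealthCheck, settings

from serpinms.glycan_model import AntennaSpec, biantennary, build_nglycan
from serpinms.proteoform_library import serpina1_sequence

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def serpina1():
    return serpina1_sequence()


@pytest.fixture
def a2g2s2():
    """Disialylated bi-antennary complex glycan, the plasma workhorse."""
    return biantennary(sialylated=True, name="A2G2S2")


@pytest.fixture
def core_fuc_a2g2s2():
    return biantennary(sialylated=True, core_fucose=True, name="A2G2S2Fc")


@pytest.fixture
def antennary_fuc_a2g2s2():
    return biantennary(sialylated=True, antennary_fucoses=1, name="A2G2S2Fa")


def complex_type_topologies(max_antennae=3):
    """All complex-type topologies with <= max_antennae antennae.

    Antenna states: bare GlcNAc; +Gal; +Gal+Neu5Ac; each optionally carrying
    an antennary fucose when galactosylated (Lewis-type epitope). Core fucose
    on/off. Used as the brute-force enumeration domain for digestion laws.
    """
    antenna_states = [
        AntennaSpec(True, False, False, False),
        AntennaSpec(True, True, False, False),
        AntennaSpec(True, True, True, False),
        AntennaSpec(True, True, False, True),
        AntennaSpec(True, True, True, True),
    ]
    for n in range(max_antennae + 1):
        for combo in itertools.combinations_with_replacement(antenna_states, n):
            for core_fuc in (False, True):
                yield build_nglycan(list(combo), core_fucose=core_fuc)
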