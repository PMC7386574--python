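import numpy as np
import pytest
from hypothesis import settings

from grasspatch import SimulationConfig, builtin_species
from grasspatch.community import Community

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def festuca():
    return builtin_species("Festuca pratensis")


@pytest.fixture(scope="session")
def poa():
    return builtin_species("Poa pratensis")


@pytest.fixture(scope="session")
def plantago():
    return builtin_species("Plantago lanceolata")


@pytest.fixture(scope="session")
def all_species(festuca, poa, plantago):
    return [festuca, poa, plantago]


@pytest.fixture
def short_config():
    return SimulationConfig(years=2)


def build_community(traits_list, widths, species_idx=None, heights=None,
                    shoot_green=None, ages=None, patch_area_cm2=10_000.0):
    """Hand-assemble a community with prescribed plant geometry for tests."""
    com = Community(traits_list, patch_area_cm2=patch_area_cm2)
    widths = np.asarray(widths, float)
    n = widths.size
    com._ensure(n)
    com.n = n
    sp = np.zeros(n, dtype=np.int64) if species_idx is None \
        else np.asarray(species_idx, dtype=np.int64)
    com.sp[:n] = sp
    com.width[:n] = widths
    hw = com.p_hw[sp]
    com.height[:n] = widths * hw if heights is None else np.asarray(heights, float)
    fs = com.p_fs[sp]
    com.sg[:n] = (0.25 * np.pi * fs * com.width[:n] ** 2 * com.height[:n]
                  if shoot_green is None else np.asarray(shoot_green, float))
    com.ss[:n] = 0.0
    com.rt[:n] = com.sg[:n] / np.array([traits_list[s].sr for s in sp])
    com.age[:n] = 400.0 if ages is None else np.asarray(ages, float)
    return com
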