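from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rdx.model import ParticleTypeSpec, SystemState, TypeRegistry

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

EXAMPLES_DIR = Path(__file__).resolve().parents[1] / "examples"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_registry():
    return TypeRegistry([
        ParticleTypeSpec("A", 1.5, 1.5, 143.1),
        ParticleTypeSpec("B", 3.0, 3.0, 71.6),
        ParticleTypeSpec("C", 3.12, 3.12, 68.82),
    ])


@pytest.fixture
def empty_state(simple_registry):
    return SystemState.empty(simple_registry, (0.0, 0.0, 0.0), (20.0, 20.0, 20.0))


def make_random_state(registry, n_per_type, box_edge, seed):
    state = SystemState.empty(registry, (0.0, 0.0, 0.0), (box_edge,) * 3)
    gen = np.random.default_rng(seed)
    for name, n in n_per_type.items():
        state.add_particles(name, gen.uniform(0, box_edge, size=(n, 3)))
    return state


@pytest.fixture
def random_state(simple_registry):
    return make_random_state(simple_registry, {"A": 30, "B": 20}, 20.0, 7)
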