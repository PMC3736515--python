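import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nutriprofile import ModelRegistry, NutrientComposition

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry() -> ModelRegistry:
    return ModelRegistry.from_dir()


@pytest.fixture(scope="session")
def uk_model(registry):
    return registry.get("uk")


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def make_composition(**overrides) -> NutrientComposition:
    """Complete composition with neutral defaults, overridable per test."""
    base = dict(
        energy_kJ=800.0,
        total_fat_g=5.0,
        saturated_fat_g=2.0,
        trans_fat_g=0.1,
        cholesterol_mg=10.0,
        total_sugar_g=8.0,
        added_sugar_g=4.0,
        sodium_mg=200.0,
        protein_g=6.0,
        fibre_g=2.0,
        fruit_veg_nut_pct=10.0,
    )
    base.update(overrides)
    return NutrientComposition(**base)
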