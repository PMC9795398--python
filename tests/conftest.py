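import pytest
from hypothesis import settings

from foodenv.records import BusinessRecord, CategoryRegistry, NutritionRecord
from foodenv.synthetic import default_categories, default_config, generate_world

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_registry():
    return CategoryRegistry(
        {"Fast Food": True, "Pizza": True, "Salad": True, "Hardware Stores": False}
    )


@pytest.fixture
def sample_businesses():
    return [
        BusinessRecord("b1", "MS", ("Fast Food", "Pizza"), 1, 4.0, 120),
        BusinessRecord("b2", "MS", ("Salad",), 2, 4.5, 30),
        BusinessRecord("b3", "CO", ("Pizza",), None, 3.5, 8),
        BusinessRecord("b4", "CO", ("Salad", "Pizza"), 3, 5.0, 300),
    ]


@pytest.fixture
def sample_nutrition():
    return [
        NutritionRecord("margherita pizza", 230.0, 100.0, "g"),
        NutritionRecord("margherita pizza", 300.0, 100.0, "grams"),
        NutritionRecord("margherita pizza", 500.0, 1.0, "slice"),
        NutritionRecord("caesar salad", 90.0, 100.0, "G "),
        NutritionRecord("chicken sandwich", 280.0, 1.0, "piece"),
    ]


def tiny_config(seed=0, **overrides):
    """A world small enough for per-test generation (<0.1 s)."""
    defaults = dict(
        n_regions=8,
        categories=tuple(default_categories(12)),
        businesses_per_region=40,
        dishes_per_category=2,
        records_per_dish=3,
        category_absence_fraction=0.15,
    )
    defaults.update(overrides)
    return default_config(seed=seed, **defaults)


@pytest.fixture
def tiny_world():
    return generate_world(tiny_config(seed=7))
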