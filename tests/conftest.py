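import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from metricfuse.data_model import (
    ClassCatalog,
    ClassifierBundle,
    LabelVector,
    ProbabilityTable,
)


@pytest.fixture
def catalog():
    return ClassCatalog(("Normal", "Pneumonia"), positive="Pneumonia")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_labels(catalog, classes, ids=None):
    ids = ids or tuple(f"s{i}" for i in range(len(classes)))
    return LabelVector(tuple(ids), tuple(classes), catalog)


def random_table(catalog, n, rng, name="clf"):
    """A valid random probability table via Dirichlet rows."""
    probs = rng.dirichlet(np.ones(len(catalog.classes)), size=n)
    ids = tuple(f"s{i}" for i in range(n))
    return ProbabilityTable(name, ids, probs, catalog)


def random_bundle(catalog, n, k, rng):
    tables = [random_table(catalog, n, rng, name=f"clf_{i}") for i in range(k)]
    return ClassifierBundle(tables)


@pytest.fixture
def small_labels(catalog):
    # P P P N N — the hand-tally example layout
    return make_labels(
        catalog, ("Pneumonia", "Pneumonia", "Pneumonia", "Normal", "Normal")
    )
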