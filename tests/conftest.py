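import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

from bgclust import (  # noqa: E402
    compute_distance,
    default_benchmark_config,
    merge_library,
    simulate_collection,
    split_by_class,
    sweep,
)


def _clustered(collection):
    library = merge_library(collection.records, collection.reference_records)
    dist = compute_distance(library)
    assignments = [
        sweep(sub, class_label=cls)[0] for cls, sub in split_by_class(dist, library).items()
    ]
    return library, dist, assignments


@pytest.fixture(scope="session")
def benchmark_collection():
    """Default recovery benchmark: 6 families / 60 BGCs, divergence <= 0.15."""
    return simulate_collection(default_benchmark_config(seed=11))


@pytest.fixture(scope="session")
def benchmark_clustered(benchmark_collection):
    return _clustered(benchmark_collection)


@pytest.fixture(scope="session")
def benchmark_library(benchmark_clustered):
    return benchmark_clustered[0]


@pytest.fixture(scope="session")
def benchmark_distance(benchmark_clustered):
    return benchmark_clustered[1]


@pytest.fixture(scope="session")
def benchmark_assignments(benchmark_clustered):
    return benchmark_clustered[2]


@pytest.fixture(scope="session")
def zerodiv_collection():
    """Same benchmark layout at divergence 0 (perfectly conserved families)."""
    return simulate_collection(default_benchmark_config(seed=11, zero_divergence=True))


@pytest.fixture(scope="session")
def zerodiv_clustered(zerodiv_collection):
    return _clustered(zerodiv_collection)
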