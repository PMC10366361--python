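import numpy as np
import pandas as pd
import pytest

from clonetrace.extract import BarcodeLibrary, CountMatrix
from clonetrace.simulate import SimulationConfig, random_library


@pytest.fixture
def rng():
    return np.random.default_rng(20230711)


@pytest.fixture
def small_library(rng):
    return random_library(50, rng)


@pytest.fixture
def small_config():
    """Desk-scale simulation small enough for per-test runs."""
    return SimulationConfig(
        n_barcodes=300,
        bottleneck_size=5000,
        full_scale_population=100_000,
        read_depth=100_000,
        seed=11,
    )


def make_count_matrix(counts: dict[str, list[int]], arms: dict[str, str]) -> CountMatrix:
    """Build a CountMatrix from per-sample count lists (barcodes implied 1..n)."""
    df = pd.DataFrame(counts)
    df.index = pd.Index(range(1, len(df) + 1), name="barcode_id")
    return CountMatrix(counts=df, arms=arms)


@pytest.fixture
def toy_matrix():
    """Three replicates + DMSO + initial, with known filter outcomes."""
    return make_count_matrix(
        {
            "initial": [10, 10, 10, 10, 10],
            "dmso": [1, 0, 9, 0, 2],
            "replicate-A": [1, 0, 100, 0, 0],
            "replicate-B": [0, 5, 80, 1, 0],
            "replicate-C": [1, 0, 120, 1, 0],
        },
        {
            "initial": "initial",
            "dmso": "dmso",
            "replicate-A": "replicate-A",
            "replicate-B": "replicate-B",
            "replicate-C": "replicate-C",
        },
    )
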