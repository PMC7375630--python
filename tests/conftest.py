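import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pcndetect import generate_city, sample_registrations


@pytest.fixture(scope="session")
def small_city():
    """Compact three-community city used across unit tests."""
    return generate_city(n_lsoa=45, n_gp=15, k=3, leakage=0.05, seed=11)


@pytest.fixture(scope="session")
def small_table(small_city):
    return sample_registrations(small_city, patients_per_lsoa=30, dup_rate=0.2, seed=12)


@pytest.fixture(scope="session")
def sealed_city():
    """Zero-leakage city: registrations never cross planted communities."""
    city = generate_city(n_lsoa=45, n_gp=15, k=3, leakage=0.0, seed=13)
    table = sample_registrations(city, patients_per_lsoa=30, dup_rate=0.0, seed=14)
    return city, table


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
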