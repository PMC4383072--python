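import numpy as np
import pytest

from rehhscan.simulate import SimulationConfig, simulate_base_population
from rehhscan.types import HaplotypeSet, MarkerMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_hapset(hap, breed="test", sample_prefix="s"):
    hap = np.asarray(hap, dtype=np.uint8)
    n = hap.shape[0] // 2
    ids = np.array([f"{sample_prefix}{i}" for i in range(n)], dtype=object)
    return HaplotypeSet(ids, breed, hap)


def make_map(n, chrom="1", spacing_bp=50_000, start=1):
    bp = start + spacing_bp * np.arange(n)
    return MarkerMap.from_arrays([f"m{i}" for i in range(n)], [chrom] * n, bp)


@pytest.fixture(scope="session")
def sim_population():
    """One medium simulated chromosome reused by several test modules."""
    cfg = SimulationConfig(n_diploids=100, chrom_length_bp=20_000_000,
                           markers_per_mb=20, generations=60, seed=7)
    hs, mmap = simulate_base_population(cfg)
    return hs, mmap
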