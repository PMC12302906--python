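import numpy as np
import pytest

from fieldfit import synthdata as sd


@pytest.fixture(scope="session")
def conditions():
    return sd.enumerate_conditions()


@pytest.fixture(scope="session")
def gc_probe(conditions):
    """Sample scaffolding over the full GC grid (no genes simulated)."""
    return sd.simulate_gc_study(conditions, [], seed=0)


@pytest.fixture(scope="session")
def small_truth(gc_probe):
    return sd.make_truth_genes(2, 2, 1, reference=gc_probe.samples, seed=42,
                               noise_sd=0.3, target_snr=6.0)


@pytest.fixture(scope="session")
def small_gc(conditions, small_truth):
    return sd.simulate_gc_study(conditions, small_truth, seed=43)


@pytest.fixture(scope="session")
def small_field(small_truth):
    return sd.simulate_field_study(small_truth, n_samples=400, seed=44)


@pytest.fixture(scope="session")
def small_test(small_truth):
    return sd.simulate_field_study(small_truth, n_samples=150, seed=45)


@pytest.fixture(scope="session")
def two_cultivar_study(conditions, small_truth):
    """GC study with two cultivars and a built-in cultivar shift for one gene."""
    shift = {"gene000": {"B": -4.0}}
    return sd.simulate_gc_study(conditions[:8], small_truth, seed=46,
                                cultivars=2, cultivar_shift=shift).study


def rng(seed=0):
    return np.random.default_rng(seed)
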