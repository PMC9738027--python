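import numpy as np
import pytest

from nhppclust.nhpp import GenomicRegion, SamplePath, constant_intensity


@pytest.fixture
def region():
    return GenomicRegion(0.0, 10.0)


@pytest.fixture
def unit_rate(region):
    return constant_intensity(1.0, region)


def homogeneous_paths(rates, region, seed=0):
    """Simulate one homogeneous path per rate (helper shared across tests)."""
    from nhppclust.nhpp import simulate_nhpp

    rng = np.random.default_rng(seed)
    return [
        simulate_nhpp(constant_intensity(r, region), region, rng, label=f"r{i}")
        for i, r in enumerate(rates)
    ]
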