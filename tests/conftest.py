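import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """A fast small-genome configuration for tests that only need structure."""
    from bulkseg.simulate import ExonSpec, SimConfig

    return SimConfig(
        seed=5,
        chromosomes=(("chr1", 5_000_000), ("chr2", 5_000_000)),
        marker_spacing=50_000,
        causative=("chr1", 2_500_000),
        deletion=("chr1", 2_400_000, 2_600_001),
        exons=ExonSpec(region_pad=50_000, n_background_genes=5),
        n_plants=240,
    )
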