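import numpy as np
import pytest

from grappa2d import SamplingScheme, evaluate_algorithms, simulate_dataset


@pytest.fixture(scope="session")
def desk_sim():
    """Default desk-scale simulation: 64^3 grid, 8 channels, noise-free."""
    return simulate_dataset(grid=64, n_channels=8)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small, fast simulation for structural tests (24^3, 4 channels)."""
    return simulate_dataset(grid=24, n_channels=4, n_segments=32)


@pytest.fixture(scope="session")
def desk_report(desk_sim):
    """nRMSE sweep on the desk-scale simulation: 4 algorithms x ACS sizes
    16/24/32 at n_x = 1, plus BK at n_x = 3, reference lines excluded."""
    ksp, _, _ = desk_sim
    schemes = [SamplingScheme(2, 2, a, a, ksp.grid_shape) for a in (16, 24, 32)]
    report = evaluate_algorithms(ksp, schemes, ("LK", "EX", "SK", "BK"),
                                 n_x_values=(1,))
    bk3 = evaluate_algorithms(ksp, [schemes[0]], ("BK",), n_x_values=(3,))
    report.entries.extend(bk3.entries)
    return report


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
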