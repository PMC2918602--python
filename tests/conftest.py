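import pytest

from mousecmr.phantom import PhantomConfig, acquire_kspace, simulate_coils
from mousecmr.protocol import AcquisitionProtocol
from mousecmr.selfgating import bin_kspace, gate_kspace


@pytest.fixture(scope="session")
def coils64():
    return simulate_coils(4, 64, 25.0)


@pytest.fixture(scope="session")
def phantom64():
    """Small two-slice phantom without respiration or noise."""
    return PhantomConfig(matrix=64, n_slices=2, resp_amplitude_mm=0.0,
                         noise_sigma_image=0.0, hrv_amplitude=0.0,
                         rrv_amplitude=0.0)


@pytest.fixture(scope="session")
def gated64(phantom64, coils64):
    """Noiseless, fully sampled, respiration-free acquisition, gated and binned.

    Shared by gating and reconstruction round-trip tests.
    """
    protocol = AcquisitionProtocol(matrix=(64, 64), repetitions=40, n_slices=2,
                                   acceleration=1.0)
    series = acquire_kspace(phantom64, protocol, coils64, noise_cov=None,
                            seed=1, nav_noise_frac=0.0)
    assignment = gate_kspace(series, resp_window=0.0)
    binned = bin_kspace(series, assignment)
    return series, assignment, binned
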