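import numpy as np
import pytest

from gpptkin import (
    FirstOrder,
    GpptKinetics,
    MichaelisMenten,
    SimConfig,
    simulate_gppt,
)

# pooled-fit ground truth used across kinetic tests (µmol l-1, µmol l-1 h-1)
KM_TRUE = 13.2
VMAX_TRUE = 55.4


@pytest.fixture(scope="session")
def noiseless_fo_dataset():
    """Noise-free first-order GPPT, k = 2 h-1, 12 extraction Ar samples."""
    cfg = SimConfig(kinetics=FirstOrder(k=2.0), noise_ch4=0.0, noise_ar=0.0,
                    n_ar_ext=12, seed=1)
    return simulate_gppt(cfg)


@pytest.fixture(scope="session")
def noiseless_mm_dataset():
    """Noise-free Michaelis-Menten GPPT at the pooled field parameters."""
    cfg = SimConfig(kinetics=MichaelisMenten(km=KM_TRUE, vmax=VMAX_TRUE),
                    noise_ch4=0.0, noise_ar=0.0, n_ar_ext=12, seed=1)
    return simulate_gppt(cfg)


@pytest.fixture(scope="session")
def noiseless_inert_dataset():
    cfg = SimConfig(kinetics=None, noise_ch4=0.0, noise_ar=0.0, n_ar_ext=10, seed=1)
    return simulate_gppt(cfg)


@pytest.fixture(scope="session")
def mm_results(noiseless_mm_dataset):
    return GpptKinetics(noiseless_mm_dataset).fit()


def exact_mm_segments(km=KM_TRUE, vmax=VMAX_TRUE, concentrations=(2.0, 5.0, 9.0, 15.0, 24.0, 36.0)):
    """Segments lying exactly on a Michaelis-Menten curve."""
    from gpptkin import SegmentRate

    return [
        SegmentRate(c_bar=c, k_local=vmax / (km + c), r_ox=vmax * c / (km + c))
        for c in concentrations
    ]
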