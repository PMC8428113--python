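import numpy as np
import pytest

from syncdecode.cohort import CouplingSpec, GroundTruth, RoiLayout, simulate_cohort
from syncdecode.spectral import FrequencyGrid

TWO_BANDS = {"alpha": (8.0, 12.0), "high_gamma": (61.0, 120.0)}


@pytest.fixture(scope="session")
def two_band_grid():
    return FrequencyGrid.from_bands(TWO_BANDS, 3)


@pytest.fixture(scope="session")
def small_layout():
    return RoiLayout.reduced(n_sub_seed=2, n_sub_target=2, n_targets=2)


@pytest.fixture(scope="session")
def null_cohort(small_layout):
    """A small cohort with no planted structure (condition-blind)."""
    truth = GroundTruth(bands=dict(TWO_BANDS))
    return simulate_cohort(
        small_layout, truth, n_subjects=4, epochs_per_condition=16,
        epoch_length=2.5, sample_rate=250.0, seed=101,
    )


@pytest.fixture(scope="session")
def planted_cohort(small_layout):
    """Cohort with one strong condition-specific coupling at high gamma."""
    lags = tuple(np.arcsin(np.linspace(-0.9, 0.9, 6)))
    truth = GroundTruth(
        couplings=[CouplingSpec(0, 2, "high_gamma", lags, kappa=50.0, amplitude=3.0)],
        bands=dict(TWO_BANDS),
    )
    return simulate_cohort(
        small_layout, truth, n_subjects=5, epochs_per_condition=32,
        epoch_length=2.5, sample_rate=250.0, seed=7,
    )
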