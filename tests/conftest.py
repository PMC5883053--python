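import warnings

import numpy as np
import pytest

from slowex import simulate
from slowex.types import (
    CESTSchedule,
    ExchangeParameters,
    ResidueSpinParameters,
    Topology,
)
from slowex.constants import NITROGEN_FREQ_500


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*baseline points.*")
        warnings.filterwarnings("ignore", message=".*outside the.*offset grid.*")
        yield


@pytest.fixture(scope="session")
def s99t_exchange():
    """Two-site exchange parameters of the single-mutant-like process."""
    return ExchangeParameters(Topology.TWO_SITE_AB, k_ex_AB=188.3,
                              p_B=0.0122)


@pytest.fixture(scope="session")
def triple_exchange():
    """Linear B<->A<->C exchange of the triple-mutant-like scenario."""
    return ExchangeParameters(Topology.LINEAR_BAC, k_ex_AB=265.1,
                              p_B=0.0432, k_ex_AC=186.5, p_C=0.0073)


@pytest.fixture
def spins():
    return ResidueSpinParameters("N102", dw_AB=2.0, R1=1.5, R2=12.0,
                                 dR2=0.0, I0=1.0, shift_ppm=118.0)


@pytest.fixture
def cest_schedule():
    return CESTSchedule(B1_field=29.7, T_EX=0.5,
                        offsets=np.linspace(110.0, 126.0, 81),
                        spectrometer_15N_freq=NITROGEN_FREQ_500)


@pytest.fixture(scope="session")
def s99t_dataset():
    """Small noisy two-site CEST dataset with known sigma, shared across
    tests that only read it."""
    truth = simulate.make_scenario("S99T-like", n_residues_per_group=4,
                                   seed=3, noise_sd=0.005)
    schedules = simulate.default_cest_schedules("S99T-like",
                                                spacing_hz=50.0)
    profiles = simulate.generate_cest_dataset(truth, schedules, seed=11)
    for p in profiles:
        p.sigma = np.full(p.ratios.shape, truth.noise_sd)
    shifts = {r: s.shift_ppm for r, s in truth.per_residue.items()}
    return truth, profiles, shifts
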