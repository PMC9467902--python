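import pytest

from hipecmd import StudyConfig, calibrate_study, correct_study, run_nca
from hipecmd.simulate import default_kinetics, simulate_study
from hipecmd.study_design import TISSUE_COMPARTMENTS


@pytest.fixture(scope="session")
def default_schedule():
    from hipecmd import build_schedule

    return build_schedule()


@pytest.fixture(scope="session")
def ideal_study():
    """Noise-free, full-recovery, no-dropout study: the identity pathway.

    Measured dialysates equal the truth-curve interval averages exactly,
    so every pipeline stage can be checked against the closed form.
    """
    config = StudyConfig(noise=False, p_malfunction=0.0, p_displaced=0.0, seed=7)
    full_recovery = {c: (100.0, 0.0) for c in TISSUE_COMPARTMENTS}
    return simulate_study(config, recovery_params=full_recovery)


@pytest.fixture(scope="session")
def ideal_nca(ideal_study):
    recovery = calibrate_study(ideal_study.calibration)
    profiles = correct_study(ideal_study.samples, recovery)
    return run_nca(profiles)


@pytest.fixture(scope="session")
def noisy_study():
    """One default-condition stochastic study (assay noise, RR draws, dropout)."""
    return simulate_study(StudyConfig(seed=42))
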