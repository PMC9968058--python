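import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ketoprog import GeneratorConfig, ProgramConfig, Subject, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def obese_subject() -> Subject:
    """W0=100 kg at 170 cm (BMI 34.6, starts in phase I), Wd=80 kg."""
    return Subject(id="obese", sex="female", age=40, height_cm=170.0,
                   initial_mass_kg=100.0, desired_mass_kg=80.0)


@pytest.fixture(scope="session")
def overweight_subject() -> Subject:
    """BMI 27.7 (overweight, not obese): fast-entry into phase IIa."""
    return Subject(id="ow", sex="male", age=35, height_cm=180.0,
                   initial_mass_kg=89.7, desired_mass_kg=72.9)


@pytest.fixture(scope="session")
def adherent_cohort():
    """69 adherent female subjects, 0.2 kg scale noise, 14-day exams."""
    config = GeneratorConfig(n_subjects=69, female_fraction=1.0,
                             non_adherence_prob=0.0, relapse_prob=0.0,
                             measurement_noise_sd=0.2, seed=1)
    subjects, exams = generate_cohort(config)
    return config, subjects, exams


@pytest.fixture(scope="session")
def default_program() -> ProgramConfig:
    return ProgramConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
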