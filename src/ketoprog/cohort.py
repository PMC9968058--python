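"""Synthetic cohorts with the anthropometric structure of a staged-diet study.

Subjects are drawn from per-sex truncated normal distributions whose
*realized* (post-truncation) mean and SD are moment-matched to the target
summary statistics by solving for the underlying normal parameters — a
naive truncated normal would otherwise overshoot the target mean when the
lower bound is close.  Height is drawn conditionally on mass so that the
baseline BMI falls inside the per-sex eligibility range (every subject
enters the program overweight or obese); the mass marginal is exact.

Examination histories evolve the true mass with the energy-balance engine,
holding the phase fixed between examinations (the phase is re-assessed at
each examination by the same rules used for prediction).  Two kinds of
protocol violation can be injected per interval:

* ``non_adherence``: complete abandonment of the prescribed intake with
  rebound overeating (intake excess ``non_adherence_extra_kcal`` above the
  phase prescription), large enough to produce net mass gain;
* ``relapse``: a mild regain episode (intake slightly above the
  maintenance requirement) that trips the phase-decrement rule without
  necessarily exceeding the 5 % deviation flag.

Measured masses add zero-mean Gaussian scale noise.  A single seeded
generator stream drives every draw, so one seed reproduces one cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .anthropometry import CIRCUMFERENCE_SITES, Subject, derive_desired_mass
from .energy_model import KG_PER_LB, CAL_PER_LB
from .errors import InvalidConfigError
from .phase_engine import ProgramConfig, make_initial_state, process_exam

__all__ = [
    "TruncatedNormalSpec",
    "SexProfile",
    "GeneratorConfig",
    "FEMALE_PROFILE",
    "MALE_PROFILE",
    "generate_subjects",
    "generate_exam_histories",
    "generate_cohort",
]


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Target realized mean/SD and hard range of one anthropometric variable."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise InvalidConfigError(f"bounds must satisfy lo < hi, got [{self.lo}, {self.hi}]")
        if not (self.lo <= self.mean <= self.hi):
            raise InvalidConfigError(
                f"target mean {self.mean} outside bounds [{self.lo}, {self.hi}]"
            )
        if self.sd <= 0:
            raise InvalidConfigError(f"sd must be positive, got {self.sd}")


@lru_cache(maxsize=128)
def _matched_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose [lo, hi]-truncation has the target moments."""

    def residual(x):
        mu, log_sigma = x
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if sol.success and max(abs(r) for r in residual(sol.x)) <= 1e-6:
        return float(sol.x[0]), float(np.exp(sol.x[1]))
    # Some printed SDs exceed what any truncated normal on [lo, hi] can
    # express (the uniform limit caps the SD at (hi-lo)/sqrt(12)).  Fall
    # back to the closest achievable SD while matching the mean exactly.
    def weighted(x):
        r = residual(x)
        return [50.0 * r[0], r[1]]

    fit = optimize.least_squares(
        weighted, x0=[mean, np.log(sd)],
        bounds=([lo - 5 * (hi - lo), np.log(sd) - 4], [hi + 5 * (hi - lo), 8.0]),
    )
    r = residual(fit.x)
    if abs(r[0]) > 1e-3:
        raise InvalidConfigError(
            f"cannot match a truncated normal mean of {mean} on [{lo}, {hi}]"
        )
    return float(fit.x[0]), float(np.exp(fit.x[1]))


def _sample_truncnorm(spec: TruncatedNormalSpec, size: int, rng: np.random.Generator,
                      lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Draw from the moment-matched truncated normal, optionally re-truncated."""
    mu, sigma = _matched_params(spec.mean, spec.sd, spec.lo, spec.hi)
    lo = spec.lo if lo is None else max(lo, spec.lo)
    hi = spec.hi if hi is None else min(hi, spec.hi)
    if not lo < hi:
        raise InvalidConfigError(f"empty truncation window [{lo}, {hi}]")
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


@dataclass(frozen=True)
class SexProfile:
    """Per-sex anthropometric targets and eligibility BMI range."""

    age: TruncatedNormalSpec
    height_cm: TruncatedNormalSpec
    mass_kg: TruncatedNormalSpec
    bmi_range: tuple[float, float]
    circumferences: dict[str, TruncatedNormalSpec] = field(default_factory=dict)

    def feasible_mass_lo(self) -> float:
        """Smallest mass compatible with the BMI floor at the shortest height.

        Lighter masses cannot yield an eligible BMI within the height range,
        so the mass distribution is matched on [max(lo, this), hi].
        """
        return self.bmi_range[0] * (self.height_cm.lo / 100.0) ** 2


# Study-cohort anthropometric summaries (baseline examination).
FEMALE_PROFILE = SexProfile(
    age=TruncatedNormalSpec(37.5, 11.1, 18, 68),
    height_cm=TruncatedNormalSpec(163.8, 7.2, 147, 184),
    mass_kg=TruncatedNormalSpec(78.6, 17.2, 52.4, 152.5),
    bmi_range=(25.3, 63.5),
    circumferences={
        "chest": TruncatedNormalSpec(88.4, 11.7, 64, 136),
        "waist_narrow": TruncatedNormalSpec(90.5, 12.9, 67, 138),
        "waist_navel": TruncatedNormalSpec(100.9, 13.5, 75, 162),
        "hips": TruncatedNormalSpec(106.7, 13.2, 79, 172),
        "biceps": TruncatedNormalSpec(33.8, 5.8, 9, 62),
        "thigh": TruncatedNormalSpec(64.9, 9.1, 28, 97),
    },
)

MALE_PROFILE = SexProfile(
    age=TruncatedNormalSpec(35.0, 11.8, 18, 56),
    height_cm=TruncatedNormalSpec(175.8, 7.4, 162, 192),
    mass_kg=TruncatedNormalSpec(103.3, 25.3, 60.3, 237),
    bmi_range=(26.3, 64.3),
    circumferences={
        "chest": TruncatedNormalSpec(99.8, 14.0, 74, 150),
        "waist_narrow": TruncatedNormalSpec(101.8, 14.7, 74, 162),
        "waist_navel": TruncatedNormalSpec(110.7, 15.8, 80, 164),
        "hips": TruncatedNormalSpec(114.9, 16.2, 80, 179),
        "biceps": TruncatedNormalSpec(37.1, 4.1, 29, 50),
        "thigh": TruncatedNormalSpec(68.5, 7.6, 56, 97),
    },
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort size, anthropometric targets, schedule, and noise/violation rates."""

    n_subjects: int = 100
    female_fraction: float = 0.69
    female: SexProfile = field(default_factory=lambda: FEMALE_PROFILE)
    male: SexProfile = field(default_factory=lambda: MALE_PROFILE)
    exam_interval: int = 14  # days
    exam_interval_jitter_sd: float = 0.0  # days; draws rounded, floored at 1
    measurement_noise_sd: float = 0.2  # kg, scale precision
    non_adherence_prob: float = 0.10  # per-interval abandonment probability
    non_adherence_extra_kcal: float = 3000.0  # intake excess during abandonment
    relapse_prob: float = 0.05  # per-interval mild-regain probability
    relapse_surplus_kcal: float = 300.0  # intake above requirement during regain
    horizon_days: int = 365  # stop histories that have not reached goal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise InvalidConfigError("n_subjects must be >= 0")
        for name in ("female_fraction", "non_adherence_prob", "relapse_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        if self.non_adherence_prob + self.relapse_prob > 1.0:
            raise InvalidConfigError("episode probabilities must sum to <= 1")
        if self.measurement_noise_sd < 0:
            raise InvalidConfigError("measurement noise SD must be >= 0")
        if self.exam_interval < 1 or self.horizon_days < 1:
            raise InvalidConfigError("exam_interval and horizon_days must be >= 1")


def _profile(config: GeneratorConfig, sex: str) -> SexProfile:
    return config.female if sex == "female" else config.male


def generate_subjects(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[Subject]:
    """Draw a cohort of eligible subjects from the per-sex profiles.

    Mass is drawn from the moment-matched truncated normal restricted to
    masses compatible with the eligibility BMI floor; height is then drawn
    conditionally so BMI lands inside the per-sex range.  The desired mass
    is the midpoint of the normal-BMI band for the drawn height.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    sexes = np.where(rng.random(config.n_subjects) < config.female_fraction,
                     "female", "male")
    for k, sex in enumerate(sexes):
        prof = _profile(config, str(sex))
        bmi_lo, bmi_hi = prof.bmi_range
        # match the mass moments on the eligibility-feasible range directly,
        # so the realized mean/SD stay on target after the BMI-floor cut
        mass_spec = prof.mass_kg
        lo_eff = max(mass_spec.lo, prof.feasible_mass_lo())
        if lo_eff > mass_spec.lo:
            mass_spec = replace(mass_spec, lo=lo_eff)
        mass = float(_sample_truncnorm(mass_spec, 1, rng)[0])
        # height window keeping BMI = mass / (h/100)^2 inside [bmi_lo, bmi_hi]
        h_lo = 100.0 * np.sqrt(mass / bmi_hi)
        h_hi = 100.0 * np.sqrt(mass / bmi_lo)
        height = float(_sample_truncnorm(prof.height_cm, 1, rng, lo=h_lo, hi=h_hi)[0])
        age = int(round(float(_sample_truncnorm(prof.age, 1, rng)[0])))
        age = min(max(age, int(prof.age.lo)), int(prof.age.hi))
        circ = {
            site: float(_sample_truncnorm(spec, 1, rng)[0])
            for site, spec in prof.circumferences.items()
            if site in CIRCUMFERENCE_SITES
        }
        subjects.append(
            Subject(
                id=f"S{k:04d}",
                sex=str(sex),
                age=age,
                height_cm=height,
                initial_mass_kg=mass,
                desired_mass_kg=derive_desired_mass(height),
                circumferences_cm=circ,
            )
        )
    return subjects


def _interval_rate(config: GeneratorConfig, program: ProgramConfig,
                   phase, episode: str) -> float:
    """True daily mass change (kg/day, positive = loss) over one interval."""
    adherent = program.daily_loss(phase)
    if episode == "adherent":
        return adherent
    if episode == "non_adherence":
        return adherent - KG_PER_LB * config.non_adherence_extra_kcal / CAL_PER_LB
    if episode == "relapse":
        return -KG_PER_LB * config.relapse_surplus_kcal / CAL_PER_LB
    raise InvalidConfigError(f"unknown episode kind {episode!r}")


def generate_exam_histories(
    subjects: list[Subject],
    config: GeneratorConfig,
    program: ProgramConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate follow-up examinations for each subject.

    Returns one row per examination with the engine's processing output
    (expected mass, phases, deviation, flags) plus the ground-truth
    ``injected`` episode label and the noise-free ``true_mass_kg``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    program = program or ProgramConfig(exam_interval=config.exam_interval)
    rows: list[dict] = []
    for subject in subjects:
        state = make_initial_state(subject, program)
        true_mass = subject.initial_mass_kg
        day = 0
        while day < config.horizon_days and not state.reached_goal:
            if config.exam_interval_jitter_sd > 0:
                t_j = int(round(rng.normal(config.exam_interval,
                                           config.exam_interval_jitter_sd)))
                t_j = max(1, t_j)
            else:
                t_j = config.exam_interval
            u = rng.random()
            if u < config.non_adherence_prob:
                episode = "non_adherence"
            elif u < config.non_adherence_prob + config.relapse_prob:
                episode = "relapse"
            else:
                episode = "adherent"
            rate = _interval_rate(config, program, state.phase, episode)
            true_mass = true_mass - rate * t_j
            noise = rng.normal(0.0, config.measurement_noise_sd) \
                if config.measurement_noise_sd > 0 else 0.0
            measured = max(true_mass + noise, 1.0)
            state, rec = process_exam(state, measured, t_j, program)
            day = rec.day
            rows.append(
                {
                    "subject_id": subject.id,
                    "sex": subject.sex,
                    "exam_index": rec.j,
                    "day": rec.day,
                    "t_j": rec.t_j,
                    "measured_mass_kg": rec.measured_mass_kg,
                    "expected_mass_kg": rec.expected_mass_kg,
                    "true_mass_kg": true_mass,
                    "phase_before": rec.phase_before,
                    "phase_after": rec.phase_after,
                    "deviation": rec.deviation,
                    "flags": ";".join(sorted(rec.flags)),
                    "injected": episode,
                }
            )
    columns = [
        "subject_id", "sex", "exam_index", "day", "t_j", "measured_mass_kg",
        "expected_mass_kg", "true_mass_kg", "phase_before", "phase_after",
        "deviation", "flags", "injected",
    ]
    return pd.DataFrame(rows, columns=columns)


def generate_cohort(
    config: GeneratorConfig, program: ProgramConfig | None = None
) -> tuple[list[Subject], pd.DataFrame]:
    """Subjects and their examination histories from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    subjects = generate_subjects(config, rng)
    exams = generate_exam_histories(subjects, config, program, rng)
    return subjects, exams
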