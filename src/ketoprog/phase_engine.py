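"""The phase-progression state machine of the staged ketogenic program.

Progress is measured as the fraction of the required loss achieved,

    p = (W0 - W_now) / (W0 - Wd),

and gates the protocol phases at 48, 64, 80, 85, 90 and 95 % (half-open
intervals, >= at each threshold).  Full programs are simulated one day at
a time; per-examination processing applies the two clinical rules:

* stagnation or gain of mass between examinations returns the subject to
  the previous phase (relapse, floored at the first phase);
* a deviation of the measured from the expected mass larger than the
  adherence tolerance (default 5 %) flags non-adherence.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .anthropometry import Subject, compute_bmi
from .energy_model import (
    DEFAULT_REQUIRED_ENERGY,
    PhaseSpec,
    daily_loss_kg,
    default_phase_table,
    step_exam_mass,
    validate_phase_table,
)
from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "ProgramConfig",
    "ExamRecord",
    "Trajectory",
    "ProgramState",
    "progress_fraction",
    "phase_for_progress",
    "initial_phase",
    "simulate_program",
    "days_to_threshold",
    "process_exam",
]


@dataclass(frozen=True)
class ProgramConfig:
    """Protocol parameters shared by simulation and examination processing."""

    phase_table: list[PhaseSpec] = field(default_factory=default_phase_table)
    mode: str = "deficit"  # "deficit" | "literal"
    required_energy: float = DEFAULT_REQUIRED_ENERGY  # kcal/day
    exam_interval: int = 14  # days between follow-up examinations
    adherence_tolerance: float = 0.05  # relative deviation flagging non-adherence
    overweight_entry_bmi: float = 30.0  # below this, start in phase IIa
    max_days: int = 1000  # simulation cap

    def __post_init__(self) -> None:
        validate_phase_table(self.phase_table)
        if self.mode not in ("deficit", "literal"):
            raise InvalidConfigError(f"mode must be 'deficit' or 'literal', got {self.mode!r}")
        if not (0.0 < self.adherence_tolerance < 1.0):
            raise InvalidConfigError("adherence tolerance must be in (0, 1)")
        if self.exam_interval < 1 or self.max_days < 1:
            raise InvalidConfigError("exam_interval and max_days must be >= 1")

    def daily_loss(self, phase: PhaseSpec) -> float:
        return daily_loss_kg(phase, self.mode, self.required_energy)


@dataclass(frozen=True)
class ExamRecord:
    """Outcome of one follow-up examination."""

    j: int  # 1-based examination index
    day: int  # days since program start
    t_j: int  # days since previous examination
    measured_mass_kg: float
    expected_mass_kg: float
    phase_before: str
    phase_after: str
    deviation: float  # |expected - measured| / expected
    flags: frozenset[str]  # subset of {non_adherent, relapse, reached_goal}


@dataclass(frozen=True)
class Trajectory:
    """Day-indexed predicted masses of a fully adherent simulated program."""

    days: list[int]
    masses_kg: list[float]
    phases: list[str]
    transition_days: dict[str, int]  # phase label -> first day in phase
    total_days: int  # days to reach Wd (== days[-1] when goal reached)
    reached_goal: bool


@dataclass(frozen=True)
class ProgramState:
    """Evolving per-subject state across examinations."""

    subject: Subject
    phase: PhaseSpec
    prev_measured_kg: float
    day: int = 0
    exam_count: int = 0
    reached_goal: bool = False
    #: fast-entry floor: progress-based selection never drops below this
    entry_phase_label: str = "I"


def progress_fraction(w0: float, wd: float, w_now: float) -> float:
    """Fraction of the required loss achieved, clamped to [0, 1]."""
    if w0 <= wd:
        raise InvalidInputError(f"need W0 > Wd, got W0={w0}, Wd={wd}")
    p = (w0 - w_now) / (w0 - wd)
    return min(1.0, max(0.0, p))


def phase_for_progress(p: float, phase_table: list[PhaseSpec] | None = None) -> PhaseSpec:
    """Highest phase whose entry threshold has been reached (half-open bins)."""
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"progress must be in [0, 1], got {p}")
    phases = phase_table if phase_table is not None else default_phase_table()
    current = phases[0]
    for phase in phases:
        if p >= phase.entry_threshold:
            current = phase
        else:
            break
    return current


def initial_phase(subject: Subject, config: ProgramConfig | None = None) -> PhaseSpec:
    """Entry phase: overweight-but-not-obese subjects skip straight to IIa.

    Subjects with BMI below ``overweight_entry_bmi`` (default 30 kg/m²,
    the conventional obesity cut-off, assigned to the obese side at the
    boundary) start in the second phase; obese subjects start in phase I.
    """
    config = config or ProgramConfig()
    bmi = compute_bmi(subject.initial_mass_kg, subject.height_cm)
    phases = config.phase_table
    if bmi < config.overweight_entry_bmi and len(phases) > 1:
        return phases[1]
    return phases[0]


def simulate_program(subject: Subject, config: ProgramConfig | None = None) -> Trajectory:
    """Simulate a fully adherent program from W0 to Wd by daily stepping.

    The phase is re-evaluated from the progress fraction every day; the
    run terminates when the mass reaches Wd (clipped, no overshoot) or at
    ``config.max_days``.
    """
    config = config or ProgramConfig()
    w0, wd = subject.initial_mass_kg, subject.desired_mass_kg
    for phase in config.phase_table:
        if config.daily_loss(phase) <= 0:
            raise InvalidConfigError(
                f"phase {phase.label} has non-positive daily loss; program cannot terminate"
            )

    days = [0]
    masses = [w0]
    start = initial_phase(subject, config)
    p0 = progress_fraction(w0, wd, w0)
    phase = phase_for_progress(p0, config.phase_table)
    if start.entry_threshold > phase.entry_threshold:
        phase = start
    phases = [phase.label]
    transitions = {phase.label: 0}
    mass = w0
    reached = mass <= wd
    day = 0
    while not reached and day < config.max_days:
        day += 1
        mass = mass - config.daily_loss(phase)
        if mass <= wd:
            mass = wd
            reached = True
        next_phase = phase_for_progress(
            progress_fraction(w0, wd, mass), config.phase_table
        )
        # never drop below the fast-entry phase for overweight subjects
        if next_phase.entry_threshold >= phase.entry_threshold:
            phase = next_phase
        days.append(day)
        masses.append(mass)
        phases.append(phase.label)
        if phase.label not in transitions:
            transitions[phase.label] = day
    return Trajectory(days, masses, phases, transitions, day, reached)


def days_to_threshold(
    w_now: float,
    w0: float,
    wd: float,
    phase: PhaseSpec,
    threshold: float,
    mode: str = "deficit",
    required_energy: float = DEFAULT_REQUIRED_ENERGY,
) -> float:
    """Continuous-time days until the progress fraction reaches ``threshold``.

    Closed-form companion of :func:`simulate_program`: the discrete daily
    simulation reaches the threshold on day ``ceil`` of this value.
    Returns 0.0 when the threshold is already passed.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InvalidInputError(f"threshold must be in [0, 1], got {threshold}")
    p_now = progress_fraction(w0, wd, w_now)
    if p_now >= threshold:
        return 0.0
    rate = daily_loss_kg(phase, mode, required_energy)
    if rate <= 0:
        raise InvalidConfigError("non-positive daily loss; threshold unreachable")
    w_at_threshold = w0 - threshold * (w0 - wd)
    return (w_now - w_at_threshold) / rate


def process_exam(
    state: ProgramState,
    measured_mass_kg: float,
    t_j: int,
    config: ProgramConfig | None = None,
) -> tuple[ProgramState, ExamRecord]:
    """Process one follow-up examination and update the program state.

    The expected mass is the staged prediction from the previously
    recorded mass under the phase in force.  Stagnation or gain
    (measured >= previous) returns the subject to the previous phase
    (relapse, floored at the first phase); otherwise the phase is
    recomputed from the progress fraction.  A relative deviation of the
    measured from the expected mass above the adherence tolerance flags
    non-adherence; reaching Wd flags goal attainment.
    """
    config = config or ProgramConfig()
    if t_j < 1:
        raise InvalidInputError(f"interval between examinations must be >= 1 day, got {t_j}")
    if measured_mass_kg <= 0:
        raise InvalidInputError(f"measured mass must be positive, got {measured_mass_kg}")
    subject = state.subject
    phases = config.phase_table
    expected = step_exam_mass(
        state.prev_measured_kg, state.phase, t_j, config.mode, config.required_energy
    )
    deviation = abs(expected - measured_mass_kg) / expected
    flags = set()
    if deviation > config.adherence_tolerance:
        flags.add("non_adherent")

    if measured_mass_kg >= state.prev_measured_kg:
        flags.add("relapse")
        idx = phases.index(state.phase)
        next_phase = phases[max(0, idx - 1)]
    else:
        p = progress_fraction(
            subject.initial_mass_kg, subject.desired_mass_kg, measured_mass_kg
        )
        next_phase = phase_for_progress(p, phases)
        # overweight fast-entry subjects are never demoted below their
        # entry phase by progress alone (only by an explicit relapse)
        entry = next(ph for ph in phases if ph.label == state.entry_phase_label)
        if next_phase.entry_threshold < entry.entry_threshold:
            next_phase = entry
    reached = measured_mass_kg <= subject.desired_mass_kg
    if reached:
        flags.add("reached_goal")

    day = state.day + t_j
    record = ExamRecord(
        j=state.exam_count + 1,
        day=day,
        t_j=t_j,
        measured_mass_kg=measured_mass_kg,
        expected_mass_kg=expected,
        phase_before=state.phase.label,
        phase_after=next_phase.label,
        deviation=deviation,
        flags=frozenset(flags),
    )
    new_state = replace(
        state,
        phase=next_phase,
        prev_measured_kg=measured_mass_kg,
        day=day,
        exam_count=state.exam_count + 1,
        reached_goal=reached,
    )
    return new_state, record


def make_initial_state(subject: Subject, config: ProgramConfig | None = None) -> ProgramState:
    """Program state at enrolment (day 0, before the first follow-up)."""
    config = config or ProgramConfig()
    start = initial_phase(subject, config)
    return ProgramState(
        subject=subject,
        phase=start,
        prev_measured_kg=subject.initial_mass_kg,
        entry_phase_label=start.label,
    )


def expected_total_days(subject: Subject, config: ProgramConfig | None = None) -> float:
    """Continuous-time bound on the program length under the slowest phase.

    Useful for choosing ``max_days``: any positive-deficit configuration
    terminates before ``required loss / min daily loss`` days.
    """
    config = config or ProgramConfig()
    min_rate = min(config.daily_loss(p) for p in config.phase_table)
    return subject.required_loss_kg / min_rate
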