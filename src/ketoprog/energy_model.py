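"""The Wishnofsky energy-balance rule and its kilogram-scale, phase-staged form.

The classical rule states that a cumulative 3500 kcal energy deficit
produces one pound of body-mass loss.  On the kilogram scale this becomes

    W(t) = W0 - 0.454 * dEB * t / 3500

with ``dEB`` the daily energy deficit (kcal/day) and ``t`` the number of
days, and in the phase-staged program the same update is iterated between
examinations, re-anchored at the previously recorded mass:

    W(t_j) = W(t_{j-1}) - 0.454 * EB_i * t_j / 3500

As printed, the staged form inserts the phase *intake* EB_i where the
closed form uses the *deficit* dEB.  Both readings are supported here:
``mode="deficit"`` (default) substitutes required_energy - intake for the
multiplier, which is the dimensionally coherent reading; ``mode="literal"``
applies the printed formula verbatim with the intake itself.

The constants 3500 kcal/lb and 0.454 kg/lb are the literal constants of
the model and are deliberately never recomputed from finer conversion
factors, so outputs are bit-comparable with the published arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import InvalidConfigError, InvalidInputError, ModelRangeError

__all__ = [
    "CAL_PER_LB",
    "KG_PER_LB",
    "KJ_PER_KCAL",
    "DEFAULT_REQUIRED_ENERGY",
    "PhaseSpec",
    "default_phase_table",
    "load_phase_table",
    "wishnofsky_loss_lb",
    "predict_mass",
    "step_exam_mass",
    "daily_loss_kg",
    "kcal_to_kj",
    "caloric_equivalent_per_kg",
]

#: Caloric equivalent of one pound of body mass, kcal/lb.
CAL_PER_LB = 3500.0
#: Pound-to-kilogram factor as used by the model (not the finer 0.45359).
KG_PER_LB = 0.454
#: Thermochemical kilocalorie, kJ/kcal.
KJ_PER_KCAL = 4.1868
#: Default required (maintenance) daily energy intake, kcal/day, used to
#: form the deficit in ``mode="deficit"``.
DEFAULT_REQUIRED_ENERGY = 2300.0

_PHASE_ORDER = ("I", "IIa", "IIb", "III", "IVa", "IVb", "V")


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of the staged ketogenic protocol.

    ``entry_threshold`` is the fraction of the required loss (W0 - Wd)
    at which the phase is entered; ``intake_kcal`` is the representative
    daily energy intake and must lie within ``kcal_range``.
    """

    label: str
    intake_kcal: float
    entry_threshold: float
    kcal_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.label not in _PHASE_ORDER:
            raise InvalidConfigError(f"unknown phase label {self.label!r}")
        if not (0.0 <= self.entry_threshold < 1.0):
            raise InvalidConfigError(
                f"entry threshold must be in [0, 1), got {self.entry_threshold}"
            )
        lo, hi = self.kcal_range
        if not (lo <= self.intake_kcal <= hi):
            raise InvalidConfigError(
                f"phase {self.label}: intake {self.intake_kcal} outside range [{lo}, {hi}]"
            )


# Flow-chart intakes with the permissible ranges of the protocol table.
_DEFAULT_PHASES: tuple[tuple[str, float, float, tuple[float, float]], ...] = (
    ("I", 800.0, 0.00, (750.0, 850.0)),
    ("IIa", 900.0, 0.48, (850.0, 950.0)),
    ("IIb", 1000.0, 0.64, (950.0, 1050.0)),
    ("III", 1150.0, 0.80, (1100.0, 1200.0)),
    ("IVa", 1300.0, 0.85, (1300.0, 1400.0)),
    ("IVb", 1400.0, 0.90, (1350.0, 1450.0)),
    ("V", 1500.0, 0.95, (1500.0, 1500.0)),
)


def default_phase_table() -> list[PhaseSpec]:
    """The seven-phase protocol: intakes 800...1500 kcal, thresholds 0...0.95."""
    return [PhaseSpec(lab, kcal, thr, rng) for lab, kcal, thr, rng in _DEFAULT_PHASES]


def validate_phase_table(phases: Sequence[PhaseSpec]) -> list[PhaseSpec]:
    """Check ordering invariants and return the table as a list."""
    phases = list(phases)
    if not phases:
        raise InvalidConfigError("phase table must not be empty")
    if phases[0].entry_threshold != 0.0:
        raise InvalidConfigError("first phase must have entry threshold 0")
    thresholds = [p.entry_threshold for p in phases]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidConfigError(f"entry thresholds must be strictly increasing: {thresholds}")
    return phases


def load_phase_table(path: str | Path | None = None) -> list[PhaseSpec]:
    """Load a phase table from a YAML/TOML file, or return the defaults.

    The file holds an ordered list of mappings with keys ``label``,
    ``intake_kcal``, ``entry_threshold`` and optionally ``kcal_range``
    (defaults to a degenerate range at the intake).
    """
    if path is None:
        return default_phase_table()
    path = Path(path)
    if not path.exists():
        return default_phase_table()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text())
    elif path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text()).get("phases")
    else:
        raise InvalidConfigError(f"unsupported phase-table format: {path.suffix}")
    if not isinstance(raw, list):
        raise InvalidConfigError(f"{path}: expected a list of phase entries")
    phases = []
    for entry in raw:
        rng = tuple(entry.get("kcal_range", (entry["intake_kcal"], entry["intake_kcal"])))
        phases.append(
            PhaseSpec(entry["label"], float(entry["intake_kcal"]),
                      float(entry["entry_threshold"]), (float(rng[0]), float(rng[1])))
        )
    return validate_phase_table(phases)


def wishnofsky_loss_lb(es_kcal_per_day: float, t_days: float) -> float:
    """Pounds lost after ``t_days`` at a daily deficit of ``es_kcal_per_day``."""
    if es_kcal_per_day < 0 or t_days < 0:
        raise InvalidInputError("deficit and duration must be non-negative")
    return es_kcal_per_day * t_days / CAL_PER_LB


def predict_mass(w0_kg: float, delta_eb: float, t_days: float) -> float:
    """Expected mass (kg) after ``t_days`` at daily deficit ``delta_eb`` kcal.

    Closed-form kilogram version of the 3500 kcal/lb rule.  Raises
    :class:`ModelRangeError` if the implied mass is non-positive.
    """
    if w0_kg <= 0:
        raise InvalidInputError(f"initial mass must be positive, got {w0_kg}")
    if delta_eb < 0 or t_days < 0:
        raise InvalidInputError("deficit and duration must be non-negative")
    w = w0_kg - KG_PER_LB * delta_eb * t_days / CAL_PER_LB
    if w <= 0:
        raise ModelRangeError(
            f"deficit {delta_eb} kcal/day over {t_days} days drives mass from "
            f"{w0_kg} kg to {w:.2f} kg; outside the model's physical range"
        )
    return w


def daily_loss_kg(
    phase: PhaseSpec,
    mode: str = "deficit",
    required_energy: float = DEFAULT_REQUIRED_ENERGY,
) -> float:
    """Per-day mass change (kg/day, positive = loss) implied by a phase.

    ``deficit`` mode uses required_energy - intake as the multiplier;
    ``literal`` mode uses the intake itself, reproducing the staged
    formula exactly as printed.
    """
    if mode == "literal":
        eb = phase.intake_kcal
    elif mode == "deficit":
        eb = required_energy - phase.intake_kcal
        if eb <= 0:
            raise InvalidConfigError(
                f"deficit mode needs required_energy > intake; got "
                f"{required_energy} <= {phase.intake_kcal} (phase {phase.label})"
            )
    else:
        raise InvalidInputError(f"mode must be 'deficit' or 'literal', got {mode!r}")
    return KG_PER_LB * eb / CAL_PER_LB


def step_exam_mass(
    w_prev_kg: float,
    phase: PhaseSpec,
    t_j_days: float,
    mode: str = "deficit",
    required_energy: float = DEFAULT_REQUIRED_ENERGY,
) -> float:
    """Expected mass at examination j from the previous recorded mass.

    One application of the staged update over the ``t_j_days`` since the
    previous examination, under the phase in force over that interval.
    """
    if w_prev_kg <= 0:
        raise InvalidInputError(f"previous mass must be positive, got {w_prev_kg}")
    if t_j_days < 0:
        raise InvalidInputError(f"interval must be non-negative, got {t_j_days}")
    w = w_prev_kg - daily_loss_kg(phase, mode, required_energy) * t_j_days
    if w <= 0:
        raise ModelRangeError(
            f"phase {phase.label} over {t_j_days} days drives mass from "
            f"{w_prev_kg} kg to {w:.2f} kg; outside the model's physical range"
        )
    return w


def kcal_to_kj(kcal: float, round_to: float = 5.0) -> float:
    """Convert kcal to kJ at 4.1868 kJ/kcal, rounded to a multiple of ``round_to``."""
    if kcal < 0:
        raise InvalidInputError(f"energy must be non-negative, got {kcal}")
    kj = kcal * KJ_PER_KCAL
    if round_to and round_to > 0:
        kj = round(kj / round_to) * round_to
    return kj


def caloric_equivalent_per_kg(rounded: bool = False) -> float:
    """Caloric equivalent of 1 kg of body mass: 3500/0.454 = 7709.25 kcal.

    With ``rounded=True`` returns the conventional value 7700 (nearest 100).
    """
    exact = CAL_PER_LB / KG_PER_LB
    if rounded:
        return round(exact / 100.0) * 100.0
    return exact
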