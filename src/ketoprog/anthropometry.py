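"""Subjects, BMI, target body mass, and dietary-composition helpers.

Heights are stored in centimetres (the unit of the source anthropometric
tables) and converted to metres internally wherever BMI is involved.
The normal-BMI band 20-25 kg/m² defines the target ("desired") body mass;
when no explicit target is given the midpoint of that band is used.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError

__all__ = [
    "Subject",
    "compute_bmi",
    "target_mass_range",
    "derive_desired_mass",
    "protein_target",
    "macronutrient_split",
    "CIRCUMFERENCE_SITES",
    "ATWATER_KCAL_PER_G",
    "MACRO_PRESETS",
]

#: Measurement sites recorded at each examination, in table order.
CIRCUMFERENCE_SITES = ("chest", "waist_narrow", "waist_navel", "hips", "biceps", "thigh")

#: Standard Atwater energy densities, kcal per gram.
ATWATER_KCAL_PER_G = {"fat": 9.0, "protein": 4.0, "carbohydrate": 4.0}

#: Macronutrient energy shares (fat, protein, carbohydrate) of the daily
#: energy intake for the two ketogenic presets.
MACRO_PRESETS = {
    "standard": {"fat": 0.70, "protein": 0.20, "carbohydrate": 0.10},
    "high_protein": {"fat": 0.60, "protein": 0.35, "carbohydrate": 0.05},
}


def compute_bmi(mass_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m².

    Parameters
    ----------
    mass_kg : float
        Body mass in kilograms, > 0.
    height_cm : float
        Standing height in centimetres, > 0.
    """
    if mass_kg <= 0 or height_cm <= 0:
        raise InvalidInputError(
            f"mass and height must be positive, got mass={mass_kg}, height={height_cm}"
        )
    h_m = height_cm / 100.0
    return mass_kg / (h_m * h_m)


def target_mass_range(
    height_cm: float, bmi_lo: float = 20.0, bmi_hi: float = 25.0
) -> tuple[float, float]:
    """Body-mass interval (kg) spanning a BMI band at the given height.

    Defaults to the normal band 20-25 kg/m² used to set the desired mass.
    """
    if height_cm <= 0:
        raise InvalidInputError(f"height must be positive, got {height_cm}")
    if not (0 < bmi_lo < bmi_hi):
        raise InvalidInputError(f"need 0 < bmi_lo < bmi_hi, got ({bmi_lo}, {bmi_hi})")
    h2 = (height_cm / 100.0) ** 2
    return bmi_lo * h2, bmi_hi * h2


def derive_desired_mass(height_cm: float) -> float:
    """Default desired mass: midpoint of the BMI 20-25 band (i.e. BMI 22.5)."""
    lo, hi = target_mass_range(height_cm)
    return 0.5 * (lo + hi)


def protein_target(
    ideal_mass_kg: float, lo: float = 1.2, hi: float = 1.5
) -> tuple[float, float]:
    """Daily protein intake band in g/day at ``lo``-``hi`` g per kg ideal mass."""
    if ideal_mass_kg <= 0:
        raise InvalidInputError(f"ideal mass must be positive, got {ideal_mass_kg}")
    if hi < lo:
        raise InvalidInputError(f"need hi >= lo, got ({lo}, {hi})")
    return ideal_mass_kg * lo, ideal_mass_kg * hi


def macronutrient_split(dei_kcal: float, preset: str = "standard") -> dict[str, float]:
    """Grams of fat/protein/carbohydrate delivering ``dei_kcal`` under a preset.

    ``standard`` is the 70:20:10 fat:protein:carbohydrate energy split;
    ``high_protein`` is 60:35:5.  Energy densities are the Atwater factors
    (9 kcal/g fat, 4 kcal/g protein and carbohydrate).
    """
    if dei_kcal < 0:
        raise InvalidInputError(f"daily energy intake must be >= 0, got {dei_kcal}")
    try:
        shares = MACRO_PRESETS[preset]
    except KeyError:
        raise InvalidInputError(
            f"unknown preset {preset!r}; expected one of {sorted(MACRO_PRESETS)}"
        ) from None
    return {
        macro: share * dei_kcal / ATWATER_KCAL_PER_G[macro]
        for macro, share in shares.items()
    }


@dataclass(frozen=True)
class Subject:
    """One program participant.

    ``desired_mass_kg`` may be omitted, in which case it is derived as the
    midpoint of the normal-BMI (20-25 kg/m²) mass range for the subject's
    height.  A subject entering the program must satisfy
    ``desired_mass_kg < initial_mass_kg``.
    """

    id: str
    sex: str  # "female" | "male"
    age: int  # years
    height_cm: float
    initial_mass_kg: float
    desired_mass_kg: float | None = None
    circumferences_cm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InvalidInputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 18:
            raise InvalidInputError(f"adult cohort: age must be >= 18, got {self.age}")
        if self.height_cm <= 0 or self.initial_mass_kg <= 0:
            raise InvalidInputError("height and initial mass must be positive")
        if self.desired_mass_kg is None:
            object.__setattr__(self, "desired_mass_kg", derive_desired_mass(self.height_cm))
        if self.desired_mass_kg <= 0:
            raise InvalidInputError("desired mass must be positive")
        if self.desired_mass_kg >= self.initial_mass_kg:
            raise InvalidInputError(
                f"desired mass {self.desired_mass_kg:.1f} kg must be below the "
                f"initial mass {self.initial_mass_kg:.1f} kg"
            )
        for site, value in self.circumferences_cm.items():
            if site not in CIRCUMFERENCE_SITES:
                raise InvalidInputError(f"unknown circumference site {site!r}")
            if value <= 0:
                raise InvalidInputError(f"circumference {site} must be positive")

    @property
    def bmi(self) -> float:
        """BMI at program start, kg/m²."""
        return compute_bmi(self.initial_mass_kg, self.height_cm)

    @property
    def required_loss_kg(self) -> float:
        """Total mass to lose, W0 - Wd."""
        return self.initial_mass_kg - self.desired_mass_kg
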