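"""Model/Results interface over the staged energy-balance predictor.

:class:`WishnofskyModel` binds a cohort (subjects plus longitudinal
examination records) to a protocol configuration; :meth:`WishnofskyModel.fit`
replays every examination through the phase engine — predicting each mass
from the previously recorded one under the phase in force — and returns a
:class:`WishnofskyResults` carrying the augmented records, per-stratum
Bland-Altman agreement and OLS calibration, and a text ``summary()``.

There are no free parameters to estimate: the model's constants are fixed
by the 3500 kcal/lb rule, so "fitting" means evaluating the mechanistic
prediction against the measurements, the way a method-comparison study
does.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import AgreementResult, bland_altman, regression_r2
from .anthropometry import Subject
from .errors import InsufficientDataError, InvalidInputError
from .io import EXAM_COLUMNS, frame_to_subjects
from .phase_engine import ProgramConfig, Trajectory, make_initial_state, process_exam, simulate_program

__all__ = ["WishnofskyModel", "WishnofskyResults"]


def _augment(subjects: list[Subject], exams: pd.DataFrame,
             config: ProgramConfig) -> pd.DataFrame:
    """Replay examinations through the engine, adding predictions and flags."""
    by_id = {s.id: s for s in subjects}
    missing = [c for c in EXAM_COLUMNS if c not in exams.columns]
    if missing:
        raise InvalidInputError(f"exam table is missing columns: {missing}")
    unknown = set(exams["subject_id"].astype(str)) - set(by_id)
    if unknown:
        raise InvalidInputError(f"exams reference unknown subjects: {sorted(unknown)[:5]}")
    rows = []
    for sid, group in exams.groupby("subject_id", sort=False):
        subject = by_id[str(sid)]
        group = group.sort_values("day")
        days = group["day"].to_numpy()
        if np.any(np.diff(days) <= 0) or days[0] <= 0:
            raise InvalidInputError(
                f"subject {sid}: examination days must be strictly increasing from day 1"
            )
        state = make_initial_state(subject, config)
        for _, row in group.iterrows():
            t_j = int(row["day"]) - state.day
            state, rec = process_exam(state, float(row["measured_mass_kg"]), t_j, config)
            out = dict(row)
            out.update(
                subject_id=str(sid),
                exam_index=int(row["exam_index"]),
                day=int(row["day"]),
                expected_mass_kg=rec.expected_mass_kg,
                phase_before=rec.phase_before,
                phase_after=rec.phase_after,
                deviation=rec.deviation,
                flags=";".join(sorted(rec.flags)),
                sex=subject.sex,
            )
            rows.append(out)
    return pd.DataFrame(rows)


@dataclass
class WishnofskyResults:
    """Agreement of staged energy-balance predictions with measured masses."""

    model: "WishnofskyModel"
    records: pd.DataFrame  # augmented examination records
    agreement: dict[str, AgreementResult]  # stratum -> Bland-Altman summary
    regression: dict[str, tuple[float, float, float]]  # stratum -> (slope, intercept, R²)

    @property
    def bias(self) -> float:
        """Pooled mean difference predicted − measured, kg."""
        return self.agreement["all"].bias

    @property
    def rsquared(self) -> float:
        """Pooled OLS R² of predicted vs measured mass."""
        return self.regression["all"][2]

    def agreement_frame(self) -> pd.DataFrame:
        """One row per stratum: n, bias, SD, limits, relative error, OLS fit."""
        rows = []
        for stratum, agr in self.agreement.items():
            slope, intercept, r2 = self.regression[stratum]
            rows.append(
                {
                    "stratum": stratum,
                    "n": agr.n,
                    "bias": agr.bias,
                    "sd_diff": agr.sd_diff,
                    "loa_low": agr.loa_low,
                    "loa_high": agr.loa_high,
                    "relative_error": agr.relative_error,
                    "r2": r2,
                    "slope": slope,
                    "intercept": intercept,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable agreement report (differences are predicted − measured)."""
        lines = [
            "Staged Wishnofsky prediction vs measured body mass",
            "=" * 58,
            f"subjects: {self.records['subject_id'].nunique()}   "
            f"examinations: {len(self.records)}",
            f"mode: {self.model.config.mode}   "
            f"required energy: {self.model.config.required_energy:.0f} kcal/day",
            "difference orientation: predicted - measured",
            "",
            f"{'stratum':<8}{'n':>6}{'bias':>9}{'SD':>8}{'LoA low':>9}"
            f"{'LoA high':>10}{'R²':>9}",
        ]
        for stratum, agr in self.agreement.items():
            r2 = self.regression[stratum][2]
            lines.append(
                f"{stratum:<8}{agr.n:>6}{agr.bias:>9.3f}{agr.sd_diff:>8.3f}"
                f"{agr.loa_low:>9.2f}{agr.loa_high:>10.2f}{r2:>9.4f}"
            )
        flagged = self.records["flags"].str.contains("non_adherent").sum()
        relapsed = self.records["flags"].str.contains("relapse").sum()
        lines += [
            "",
            f"non-adherent examinations (deviation > "
            f"{self.model.config.adherence_tolerance:.0%}): {flagged}",
            f"relapse examinations (stagnation/gain): {relapsed}",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, stratum: str = "all", ax=None):
        """Bland-Altman scatter with bias and limits of agreement."""
        import matplotlib.pyplot as plt

        agr = self.agreement[stratum]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(agr.pair_means, agr.differences, s=12, alpha=0.6,
                   edgecolors="none")
        for y, style, label in (
            (agr.bias, "-", f"bias {agr.bias:+.3f} kg"),
            (agr.loa_low, "--", f"LoA {agr.loa_low:+.2f} kg"),
            (agr.loa_high, "--", f"LoA {agr.loa_high:+.2f} kg"),
        ):
            ax.axhline(y, linestyle=style, color="k", linewidth=1)
            ax.annotate(label, xy=(1.0, y), xycoords=("axes fraction", "data"),
                        fontsize=8, ha="right", va="bottom")
        ax.set_xlabel("mean of predicted and measured mass [kg]")
        ax.set_ylabel("predicted − measured [kg]")
        ax.set_title(f"Bland-Altman agreement ({stratum})")
        return ax


class WishnofskyModel:
    """Staged energy-balance body-mass predictor bound to a cohort.

    Parameters
    ----------
    subjects : list of Subject
        Program participants (initial and desired mass, anthropometrics).
    exams : DataFrame
        Longitudinal records with columns subject_id, exam_index, day,
        measured_mass_kg (day 0 is program start; days strictly increasing).
    config : ProgramConfig, optional
        Phase table, prediction mode, required energy, tolerances.
    """

    def __init__(self, subjects: list[Subject], exams: pd.DataFrame,
                 config: ProgramConfig | None = None) -> None:
        self.subjects = list(subjects)
        self.exams = exams.copy()
        self.config = config or ProgramConfig()

    @classmethod
    def from_dataframes(cls, subjects: pd.DataFrame, exams: pd.DataFrame,
                        config: ProgramConfig | None = None) -> "WishnofskyModel":
        """Build from subjects.csv / exams.csv-schema frames."""
        return cls(frame_to_subjects(subjects), exams, config)

    @classmethod
    def from_csv(cls, subjects_path, exams_path,
                 config: ProgramConfig | None = None) -> "WishnofskyModel":
        from .io import read_exams, read_subjects

        return cls(read_subjects(subjects_path), read_exams(exams_path), config)

    def fit(self) -> WishnofskyResults:
        """Predict every examination and evaluate agreement per sex stratum."""
        records = _augment(self.subjects, self.exams, self.config)
        if len(records) < 3:
            raise InsufficientDataError(
                f"need at least 3 examinations to evaluate agreement, got {len(records)}"
            )
        strata: dict[str, pd.DataFrame] = {"all": records}
        for sex, group in records.groupby("sex"):
            strata[str(sex)] = group
        agreement, regression = {}, {}
        for name, group in strata.items():
            if len(group) < 3:
                continue
            pred = group["expected_mass_kg"].to_numpy()
            meas = group["measured_mass_kg"].to_numpy()
            agreement[name] = bland_altman(pred, meas)
            regression[name] = regression_r2(meas, pred)
        return WishnofskyResults(self, records, agreement, regression)

    def simulate(self, subject_id: str | None = None) -> dict[str, Trajectory]:
        """Fully adherent daily trajectories for one or all subjects."""
        chosen = [s for s in self.subjects if subject_id in (None, s.id)]
        if not chosen:
            raise InvalidInputError(f"unknown subject id {subject_id!r}")
        return {s.id: simulate_program(s, self.config) for s in chosen}
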