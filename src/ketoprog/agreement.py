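"""Method-agreement and descriptive statistics for predicted vs. measured mass.

Bland-Altman analysis summarises paired predictions and measurements by
the mean difference (bias) and the limits of agreement bias ± 1.96 × SD
of the differences; pairs outside the limits are reported as outliers.
The difference orientation is predicted − measured throughout and is
recorded on the result object.  Ordinary least squares (R²) and simple
descriptive summaries complete the evaluation toolkit.

All standard deviations use the sample (n−1) convention.  The
``relative_error`` field is the SD of the relative differences
(predicted − measured) / measured, a dimensionless per-pair error scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, InvalidInputError

__all__ = [
    "AgreementResult",
    "bland_altman",
    "regression_r2",
    "descriptive_summary",
    "frequency_table",
]

#: Two-sided 95% normal quantile used for the limits of agreement.
LOA_Z = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of paired predicted/measured values.

    ``orientation`` documents the sign convention of the differences.
    """

    n: int
    bias: float  # mean(predicted - measured), kg
    sd_diff: float  # sample SD of the differences, kg
    loa_low: float  # bias - 1.96 * sd_diff
    loa_high: float  # bias + 1.96 * sd_diff
    relative_error: float  # SD of (predicted - measured) / measured
    outlier_indices: tuple[int, ...] = ()
    orientation: str = "predicted - measured"
    # pairwise means, kept for plotting only
    pair_means: tuple[float, ...] = field(default=(), repr=False)
    differences: tuple[float, ...] = field(default=(), repr=False)


def bland_altman(predicted, measured) -> AgreementResult:
    """Bland-Altman agreement of predicted against measured values.

    Differences are predicted − measured; limits of agreement are
    bias ± 1.96 × sample SD of the differences; outliers are exactly the
    pairs whose difference lies outside the limits.
    """
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if pred.shape != meas.shape or pred.ndim != 1:
        raise InvalidInputError("predicted and measured must be 1-D and of equal length")
    n = pred.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    d = pred - meas
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rel = d / meas
    rel_err = float(rel.std(ddof=1))
    lo, hi = bias - LOA_Z * sd, bias + LOA_Z * sd
    outliers = tuple(int(i) for i in np.nonzero(np.abs(d - bias) > LOA_Z * sd)[0])
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        relative_error=rel_err,
        outlier_indices=outliers,
        pair_means=tuple((pred + meas) / 2.0),
        differences=tuple(d),
    )


def regression_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares fit of y on x: (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in x; regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2


def descriptive_summary(values) -> dict[str, float]:
    """Mean, sample SD, mode (most frequent, smallest on ties), min, max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty series")
    uniq, counts = np.unique(v, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.unique sorts: ties break smallest
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "mean": float(v.mean()),
        "sd": sd,
        "mode": mode,
        "min": float(v.min()),
        "max": float(v.max()),
    }


def frequency_table(categories, decimals: int = 2) -> dict[str, float]:
    """Relative frequencies (%) of a categorical series, rounded to 2 decimals."""
    cats = list(categories)
    if not cats:
        raise InsufficientDataError("empty series")
    vals, counts = np.unique(np.asarray(cats), return_counts=True)
    total = counts.sum()
    return {str(v): round(100.0 * c / total, decimals) for v, c in zip(vals, counts)}
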