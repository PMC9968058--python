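"""Exception hierarchy for ketoprog.

All errors derive from :class:`KetoprogError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad user input, bad configuration, non-physical model output, and data
that is too small or degenerate for a statistic.
"""


class KetoprogError(Exception):
    """Base class for all ketoprog errors."""


class InvalidInputError(KetoprogError, ValueError):
    """A function argument violates its precondition (sign, range, category)."""


class InvalidConfigError(KetoprogError, ValueError):
    """A program or generator configuration is internally inconsistent."""


class ModelRangeError(KetoprogError, ValueError):
    """The energy-balance model produced a non-physical result (mass <= 0)."""


class InsufficientDataError(KetoprogError, ValueError):
    """A statistic was requested on fewer observations than it needs."""


class DegenerateFitError(KetoprogError, ValueError):
    """A regression cannot be fitted (e.g. zero variance in the regressor)."""
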