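"""Exception hierarchy.

Every failure mode gets a distinct class so callers (and the CLI) can
react to "your parameters are invalid" differently from "your dataset
cannot support this statistic".
"""


class EpibenchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EpibenchError, ValueError):
    """A model or function parameter is outside its admissible domain."""


class EffectRangeError(EpibenchError, ValueError):
    """An observed effect falls outside [0, 1] (or [0, 100] %) under strict policy."""


class DegenerateDataError(EpibenchError, ValueError):
    """Too few effectively weighted points, empty input, or all weights zero."""


class UndefinedCorrelationError(EpibenchError, ValueError):
    """Weighted variance of X or Y is zero, so the correlation is undefined.

    Deliberately distinct from :class:`DegenerateDataError`: zero variance
    and zero total weight are different pathologies of entropy weighting.
    """


class SchemaError(EpibenchError, ValueError):
    """A CSV export lacks required columns (lists the unresolved fields)."""


class UnitError(EpibenchError, ValueError):
    """A quantitative measurement's units are not recognized as a percentage."""


class FitError(EpibenchError, RuntimeError):
    """Parameter recovery failed (non-convergence or uninformative data)."""


class FixtureSpecError(EpibenchError, ValueError):
    """A synthetic-fixture specification is internally inconsistent."""
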