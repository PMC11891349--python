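"""Exception hierarchy shared across the package."""


class CpgenError(Exception):
    """Base class for all package-specific errors."""


class SpecificationError(CpgenError, ValueError):
    """An invalid generator or pipeline specification."""


class TaskError(CpgenError, ValueError):
    """An operation applied to a dataset of the wrong task type."""


class LeakageError(CpgenError, ValueError):
    """Sample identifiers shared between sets that must be disjoint."""


class CalibrationCoverageError(CpgenError, ValueError):
    """A Mondrian category with no calibration examples."""


class TableFormatError(CpgenError, ValueError):
    """A malformed expression table on disk."""
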