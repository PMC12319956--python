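"""Exception hierarchy shared across afidreg."""


class AfidRegError(Exception):
    """Base class for all afidreg errors."""


class InputError(AfidRegError):
    """Invalid or malformed user input (files, tables, configuration)."""


class FcsvParseError(InputError):
    """A Slicer markups fiducial file could not be parsed."""


class TransformError(InputError):
    """A transform file or transform application is invalid."""


class OutOfBoundsError(TransformError):
    """A point fell outside a displacement field's grid."""


class DegenerateStatisticsError(AfidRegError):
    """A statistic could not be computed (zero variance, too few samples)."""
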