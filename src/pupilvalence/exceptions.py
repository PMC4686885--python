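"""Exception hierarchy shared by all pupilvalence modules."""


class PupilError(Exception):
    """Base class for all errors raised by pupilvalence."""


class FormatError(PupilError):
    """An on-disk table is malformed (missing column, bad dialect)."""


class DataError(PupilError):
    """The data violate a precondition (non-monotone time, empty trace, ...)."""


class ParameterError(PupilError):
    """A configuration or function parameter is invalid."""
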