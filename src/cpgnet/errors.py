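"""Exception hierarchy shared by all pipeline stages."""


class CpgnetError(Exception):
    """Base class for all errors raised by cpgnet."""


class FormatError(CpgnetError):
    """An input file is malformed (missing column, bad field, self-loop)."""


class ReferentialError(CpgnetError):
    """A record refers to an entity that does not exist."""


class MappingError(CpgnetError):
    """A raw tissue name has no organ-system mapping."""


class UsageError(CpgnetError):
    """An operation was called with invalid arguments or out of order."""


class ParameterError(UsageError):
    """Synthetic-data generator parameters are infeasible."""


class DataError(CpgnetError):
    """Data violate a documented invariant."""
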