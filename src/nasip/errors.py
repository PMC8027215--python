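"""Exception hierarchy."""


class NasipError(Exception):
    """Base class for all package errors."""


class DomainError(NasipError, ValueError):
    """A numeric argument lies outside its physical domain."""


class TableFormatError(NasipError, ValueError):
    """A fraction-table file or object violates the format contract."""
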