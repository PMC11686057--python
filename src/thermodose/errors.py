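"""Exception hierarchy shared across the pipeline."""


class ThermodoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermodoseError):
    """A parameter combination is physically or numerically invalid."""


class DomainError(ThermodoseError, ValueError):
    """An input lies outside the domain the operation is defined on."""


class UsageError(ThermodoseError, ValueError):
    """The operation was called with arguments that make it ill-posed."""


class FormatError(ThermodoseError):
    """A file or file pair does not conform to the expected on-disk format."""
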