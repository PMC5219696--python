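"""Exception types shared across the package."""


class CmzPKError(Exception):
    """Base class for package errors."""


class InvalidInputError(CmzPKError, ValueError):
    """An argument violates a physiological or mathematical precondition."""


class InvalidModelError(CmzPKError, ValueError):
    """A structural model produced a non-physical parameter value."""


class ConfigError(CmzPKError, ValueError):
    """A configuration object is internally inconsistent."""


class DataError(CmzPKError, ValueError):
    """A dataset violates the expected longitudinal layout."""
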