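"""Exception hierarchy: configuration errors vs data errors.

The CLI maps :class:`ConfigurationError` and :class:`DataError` to distinct
exit codes, so keep the split meaningful when raising.
"""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError):
    """A config/dialect/parameter problem (bad key, missing path, bad value)."""


class DataError(PipelineError):
    """Malformed or inconsistent input data."""


class VcfParseError(DataError):
    pass


class PedigreeError(DataError):
    pass
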