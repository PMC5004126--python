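"""Exception hierarchy."""


class StreamModesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StreamModesError):
    """An invalid combination of configuration values."""


class InputError(StreamModesError):
    """Malformed or unusable input data."""


class DegenerateSampleError(StreamModesError):
    """A sample without enough variation for the requested statistic."""
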