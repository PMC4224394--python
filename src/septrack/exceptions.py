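"""Exception hierarchy."""


class SeptrackError(Exception):
    """Base class for all septrack errors."""


class ConfigurationError(SeptrackError, ValueError):
    """Invalid simulation or analysis configuration."""


class DegenerateInputError(SeptrackError, ValueError):
    """Input data that is structurally unusable (e.g. an all-zero frame)."""


class InputError(SeptrackError, ValueError):
    """Malformed table or array input."""
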