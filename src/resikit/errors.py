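"""Exception hierarchy shared across the toolkit."""


class ResiError(Exception):
    """Base class for all resikit errors."""


class FormatError(ResiError):
    """A file does not conform to the expected localization-table dialect."""


class ValidationError(ResiError):
    """Input data or parameters violate a documented invariant."""
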