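"""Error types shared across the pipeline stages."""


class MielmError(Exception):
    """Base class for all structured errors raised by this package."""


class UsageError(MielmError, ValueError):
    """A caller violated an operation's precondition (bad argument, bad config)."""


class DataError(MielmError):
    """Input data cannot be used (unreadable file, empty epoch set, bad values)."""
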