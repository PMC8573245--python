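"""Exception hierarchy shared across the package."""


class KhknnError(Exception):
    """Base class for all errors raised by this package."""


class InputError(KhknnError, ValueError):
    """Malformed caller input: shape mismatch, out-of-range value, bad file cell."""


class ConfigError(KhknnError, ValueError):
    """Invalid configuration: bad kernel bandwidth, non-positive regularization."""


class DataError(KhknnError, ValueError):
    """Data violates a structural precondition (e.g. an empty class)."""


class ProtocolError(KhknnError, RuntimeError):
    """An evaluation protocol cannot proceed (e.g. a jackknife fold lost a class)."""
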