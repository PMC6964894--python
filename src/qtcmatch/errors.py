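"""Exception types shared across the package."""


class QTCMatchError(ValueError):
    """Base class for all validation and usage errors raised by qtcmatch."""


class ValidationError(QTCMatchError):
    """Invalid input data (file contents, coordinates, sampling)."""


class RosterMismatchError(QTCMatchError):
    """Two sequences or matrices do not share the same object roster."""
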