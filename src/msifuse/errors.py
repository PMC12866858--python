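"""Exception hierarchy shared across the package."""


class MsiFuseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MsiFuseError):
    """A file does not conform to its declared external format."""


class IntegrityError(MsiFuseError):
    """A file parses but violates its own internal declarations."""


class ParseError(FormatError):
    """A cell/field could not be parsed; carries row/col position."""

    def __init__(self, message: str, row: int | None = None, col: int | None = None):
        super().__init__(message)
        self.row = row
        self.col = col


class DataError(MsiFuseError):
    """In-memory data violates a numeric contract (e.g. non-finite values)."""


class RegistrationError(MsiFuseError):
    """Microscopy and ion-image shapes violate the registration contract."""


class CheckpointError(MsiFuseError):
    """A checkpoint file is unreadable, tampered, or from a different config."""
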