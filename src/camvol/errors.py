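"""Exception hierarchy for camvol."""


class CamvolError(Exception):
    """Base class for all camvol errors."""


class ConfigurationError(CamvolError):
    """Invalid configuration values (bounds, counts, probabilities)."""


class PlacementError(CamvolError):
    """A nodule could not be placed on the image grid."""


class FormatError(CamvolError):
    """Malformed input file (image or table)."""


class SingularFitError(CamvolError):
    """Design matrix is rank deficient after column scaling."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ModelError(CamvolError):
    """Inconsistent model specification (e.g. coefficient count mismatch)."""


class DataIntegrityError(CamvolError):
    """Input table violates a structural contract (duplicates, missing keys)."""


class DomainError(CamvolError):
    """Operation applied outside its mathematical domain."""
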