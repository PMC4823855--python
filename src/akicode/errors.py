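"""Exception types raised across the package."""


class AkicodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AkicodeError):
    """A parameter set is internally inconsistent or infeasible."""


class DataIntegrityError(AkicodeError):
    """Input tables violate a structural invariant (referential integrity,
    duplicated most-responsible diagnosis, mismatched case sets, ...)."""


class InconsistentCountsError(AkicodeError):
    """Planted or reconstructed 2x2 counts contradict each other or the
    printed marginals they were derived from."""


class AmbiguousCountsError(AkicodeError):
    """More than one 2x2 table is consistent with a printed row."""

    def __init__(self, message, candidates):
        super().__init__(message)
        self.candidates = candidates
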