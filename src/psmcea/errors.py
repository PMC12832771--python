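"""Exception hierarchy for the psmcea pipeline."""


class PsmCeaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PsmCeaError):
    """Invalid or incomplete configuration (unknown family, missing price, ...)."""


class DataError(PsmCeaError):
    """Input data violates a documented invariant beyond repair tolerance."""


class FittingError(PsmCeaError):
    """Maximum-likelihood estimation failed or hit a boundary."""


class ReconstructionError(PsmCeaError):
    """Pseudo-IPD reconstruction constraints are infeasible."""
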