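"""Exception taxonomy shared across the package."""


class GsmonoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GsmonoError):
    """Invalid run configuration, geometry parameters, or presets."""


class ContractViolation(GsmonoError):
    """An in-package API contract was violated (shape/domain mismatch)."""


class DomainOverflowError(GsmonoError):
    """A Lagrangian point left the ghost box (or came within kernel support
    of its edge), so spreading/interpolation would read outside the grid."""


class NumericalError(GsmonoError):
    """Blow-up, singular system, or other numerical failure, with context."""


class InsufficientDataError(GsmonoError):
    """An estimator did not observe enough events (e.g. front passes)."""
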