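"""Exception hierarchy shared across the package."""


class RelaxkitError(Exception):
    """Base class for all package errors."""


class FormatError(RelaxkitError):
    """A file does not conform to the expected format or identifiers."""


class CoordinateError(RelaxkitError):
    """A requested interval lies outside the target sequence."""


class UndefinedContentError(RelaxkitError):
    """A sequence composition statistic is undefined (empty or all-N input)."""


class InputError(RelaxkitError):
    """An in-memory argument violates a precondition (e.g. unknown residue)."""


class ConfigError(RelaxkitError):
    """A configuration value is inconsistent or infeasible."""


class BuoyancyError(RelaxkitError):
    """The buoyancy term (1 - vbar*rho) is non-positive; the species does not sediment."""


class FitError(RelaxkitError):
    """A nonlinear fit failed to converge."""
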