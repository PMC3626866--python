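"""Exception hierarchy for strainopt."""


class StrainOptError(Exception):
    """Base class for all strainopt errors."""


class ParseError(StrainOptError):
    """A model or table file could not be parsed; the message names the offending record."""


class ValidationError(StrainOptError):
    """A domain object violates one of its invariants."""


class ConfigurationError(StrainOptError):
    """Inconsistent settings, e.g. an eligible reaction without a capacity distribution."""


class InfeasibleError(StrainOptError):
    """A constraint set admits no solution.

    Carries ``diagnostics``: a human-readable account of the constraints
    that are jointly unsatisfiable (e.g. the binding measurements).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class UnboundedError(StrainOptError):
    """An LP objective is unbounded; the message names the runaway flux."""


class ResourceError(StrainOptError):
    """A combinatorial guard tripped (too many elementary modes, too large an enumeration)."""
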