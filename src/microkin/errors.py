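"""Exception hierarchy.

Every domain failure raises a subclass of :class:`MicrokinError`, so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class MicrokinError(Exception):
    """Base class for all domain errors raised by this package."""


class ParseError(MicrokinError):
    """A text input did not match the expected grammar."""


class TruncatedFileError(ParseError):
    """A file ended before the declared amount of data was read."""


class UnknownElementError(ParseError):
    """An element symbol is not in the periodic table."""


class MissingEnergyError(ParseError):
    """A quantum-chemistry output carried no final-energy line."""


class SchemaError(MicrokinError):
    """A mechanism JSON document violates the schema."""


class MechanismReferenceError(SchemaError):
    """A mechanism entry points at a species that is not declared."""


class DomainError(MicrokinError):
    """A numeric argument is outside its physical domain (T <= 0, ...)."""


class GeometryError(MicrokinError):
    """A geometry is degenerate for the requested operation."""


class CompositionError(MicrokinError):
    """An operation would compare states of unbalanced composition."""


class ValidationError(MicrokinError):
    """A record fails a consistency check (e.g. >1 imaginary mode)."""


class StateError(MicrokinError):
    """Required thermochemical state data is missing."""


class SolverError(MicrokinError):
    """The ODE integrator failed; carries the last good state."""

    def __init__(self, message, times=None, conc=None):
        super().__init__(message)
        self.times = times
        self.conc = conc


class FitError(MicrokinError):
    """A regression could not be performed on the measured rates."""


class UndefinedSelectivityError(MicrokinError):
    """Selectivity is 0/0: every competing concentration is zero."""
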