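"""Exception hierarchy for the cbmap package."""


class CBMapError(Exception):
    """Base class for all cbmap errors."""


class InputError(CBMapError, ValueError):
    """Invalid user input (bad coordinates, mixed traits, bad factors...)."""


class FitError(CBMapError, ValueError):
    """A regression fit could not be performed (singular design, too few rows)."""


class DomainError(CBMapError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class ExtrapolationError(CBMapError, ValueError):
    """A prediction was requested outside a model's validity interval."""


class MapFormatError(CBMapError, ValueError):
    """A serialized map file is malformed or inconsistent."""


class InsufficientDataError(CBMapError, ValueError):
    """Too few paired observations to carry out an analysis."""
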