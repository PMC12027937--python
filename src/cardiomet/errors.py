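"""Exception hierarchy.

``ValidationError`` covers bad data or bad arguments, ``ConfigurationError``
covers missing/unknown configuration (equations, analytes, presets), and
``GenerationError`` covers failures of the synthetic-cohort sampler.
"""


class CardiometError(Exception):
    """Base class for all package errors."""


class ValidationError(CardiometError, ValueError):
    """Invalid input data or arguments."""


class ConfigurationError(CardiometError):
    """Missing or inconsistent configuration."""


class GenerationError(CardiometError):
    """Synthetic-cohort sampling could not satisfy its constraints."""
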