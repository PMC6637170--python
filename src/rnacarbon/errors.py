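"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (see :mod:`rnacarbon.cli`):
validation errors → 3, I/O errors → 4, configuration errors → 5.
"""


class RnaCarbonError(Exception):
    """Base class for all package errors."""


class ValidationError(RnaCarbonError, ValueError):
    """Invalid scientific input (bad measurement, bad table contents)."""


class InvalidMeasurementError(ValidationError):
    """Fraction modern non-positive or below measurement background."""


class InvalidYearError(ValidationError):
    """Measurement year before the 1950 radiocarbon reference."""


class OutOfRangeError(ValidationError):
    """A value outside its mathematically meaningful domain."""


class DegenerateEndmembersError(ValidationError):
    """The two mixing end-members coincide; the fraction is undefined."""


class EmptyGroupError(ValidationError):
    """A protocol-group filter matched no records."""

    def __init__(self, filters):
        self.filters = dict(filters)
        super().__init__(f"no records match filters: {self.filters}")


class InputIOError(RnaCarbonError, OSError):
    """A required input file is missing or unparseable."""


class PackagingError(RnaCarbonError):
    """A bundled fixture failed its integrity check."""


class ConfigurationError(RnaCarbonError):
    """Inconsistent configuration (e.g. missing DIC end-member)."""
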