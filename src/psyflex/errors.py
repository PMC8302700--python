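"""Exception hierarchy shared across modules."""


class PsyflexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PsyflexError, ValueError):
    """Invalid generator or run configuration (bad probability, n too small, ...)."""


class ValidationError(PsyflexError, ValueError):
    """Malformed input data (wrong item count, non-binary responses, ...)."""


class ParameterError(PsyflexError, ValueError):
    """Model parameter outside its admissible support."""


class StructuralError(PsyflexError, ValueError):
    """Structurally inconsistent inputs (wrong trial count, mismatched subjects)."""


class DegenerateInputError(PsyflexError, ValueError):
    """Input with no usable variation (zero variance, empty group)."""


class MissingDataError(PsyflexError, ValueError):
    """Required cells or ratings are absent."""


class NotScorableError(PsyflexError, ValueError):
    """Scenario or record is not eligible for scoring (e.g. a distractor)."""


class SingularModelError(PsyflexError, ValueError):
    """Design matrix is rank deficient; carries the names of collinear terms."""

    def __init__(self, message: str, collinear_terms: list[str] | None = None):
        super().__init__(message)
        self.collinear_terms = collinear_terms or []


class ScheduleGenerationError(PsyflexError, RuntimeError):
    """Pseudorandomisation retry cap exceeded; carries the offending seed."""

    def __init__(self, message: str, seed: int | None = None):
        super().__init__(message)
        self.seed = seed


class FitError(PsyflexError, RuntimeError):
    """Model fitting failed or did not converge."""
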