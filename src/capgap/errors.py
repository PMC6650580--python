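"""Exception hierarchy shared across the package."""


class CapGapError(Exception):
    """Base class for all package-specific errors."""


class ModelError(CapGapError):
    """Structural problem in a musculoskeletal model (bad references, cycles)."""


class DomainError(CapGapError, ValueError):
    """Input outside its documented domain (coordinate range, activation bounds)."""


class InfeasibleGeometryError(CapGapError):
    """Rigid-tendon fiber length would be non-positive (l_mt <= l_ts)."""

    def __init__(self, muscle: str, l_mt: float, l_ts: float):
        self.muscle = muscle
        super().__init__(
            f"infeasible geometry for muscle {muscle!r}: "
            f"musculotendon length {l_mt:.6g} m <= tendon slack length {l_ts:.6g} m"
        )


class FormatError(CapGapError):
    """Malformed input file; carries a line number where available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(CapGapError):
    """Inconsistent configuration (missing mapping, mismatched names)."""


class SurgeryError(CapGapError):
    """A virtual surgery cannot be applied as parameterized."""
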