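"""Exception hierarchy for the photothermal package."""


class PhotothermalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhotothermalError):
    """An input table is missing a mandatory column or violates the schema."""


class TableParseError(PhotothermalError, ValueError):
    """A cell could not be parsed; carries the offending row where known."""


class DomainError(PhotothermalError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UndefinedHueError(DomainError):
    """Hue angle is undefined at the achromatic point a* = b* = 0."""


class SingularDesignError(PhotothermalError):
    """The regression design matrix is rank deficient.

    ``collinear_terms`` names the offending columns when identifiable.
    """

    def __init__(self, message: str, collinear_terms: tuple[str, ...] = ()):
        super().__init__(message)
        self.collinear_terms = collinear_terms


class InsufficientDataError(PhotothermalError):
    """Too few observations to estimate the requested model."""


class NoOptimumError(PhotothermalError):
    """The surface has no stationary point in the requested direction
    (the relevant quadratic coefficient is absent or zero)."""


class ConfigError(PhotothermalError):
    """A pipeline configuration file failed validation."""


class PipelineStageError(PhotothermalError):
    """A pipeline stage failed; carries the stage and the species/trait."""

    def __init__(self, stage: str, species: str | None, trait: str | None,
                 cause: BaseException):
        super().__init__(
            f"pipeline stage {stage!r} failed"
            + (f" for {species}/{trait}" if species else "")
            + f": {cause}"
        )
        self.stage = stage
        self.species = species
        self.trait = trait
        self.cause = cause


class DegenerateVarianceWarning(UserWarning):
    """The response is constant; R² is reported as 0 by convention."""


class TruncationWarning(UserWarning):
    """Simulated draws were truncated to respect a physical bound."""
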