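"""Exception hierarchy for the corrtaste pipeline."""


class CorrtasteError(Exception):
    """Base class for all package errors."""


class ParameterError(CorrtasteError, ValueError):
    """Invalid parameter value (bad fractions, negative noise, empty input...)."""


class PackingError(CorrtasteError):
    """The requested number of cells cannot be packed into the bud footprint."""


class ChannelBudgetError(CorrtasteError):
    """More payload channels requested for a round than the spectral budget allows."""


class DegenerateBaselineError(CorrtasteError):
    """Baseline window has zero variance; Z-scores are undefined."""


class DegenerateReferenceError(CorrtasteError):
    """Motion-correction reference image carries no signal."""


class DegenerateContentError(CorrtasteError):
    """Image content is featureless; registration cannot be anchored."""


class ConvergenceError(CorrtasteError):
    """Iterative registration failed to converge; carries the residual report."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GeometryError(CorrtasteError):
    """Coordinates fall outside the expected frame, or a region is empty."""


class ConsistencyError(CorrtasteError):
    """Cross-table indices disagree (labels present in one modality only...)."""


class ConfigurationError(CorrtasteError):
    """Pipeline or operation configuration incomplete."""


class DependencyError(CorrtasteError):
    """A pipeline stage is missing the output of an upstream stage."""


class ValidationError(CorrtasteError):
    """A loaded artifact violates its type invariants."""
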