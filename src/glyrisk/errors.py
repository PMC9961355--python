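"""Exception hierarchy shared across the package."""


class GlyriskError(Exception):
    """Base class for all package errors."""


class FormatError(GlyriskError, ValueError):
    """Input file could not be parsed."""


class InsufficientDataError(GlyriskError, ValueError):
    """Fewer usable data points than the operation requires."""


class EmptySeriesError(GlyriskError, ValueError):
    """A series contains no valid point at all."""


class DomainError(GlyriskError, ValueError):
    """Argument outside the mathematical domain of a transform."""


class ContractError(GlyriskError, ValueError):
    """A precondition on an operation's inputs was violated."""


class ConfigError(GlyriskError, ValueError):
    """Invalid configuration value."""


class DivergenceError(GlyriskError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class UndefinedMetricError(GlyriskError, ValueError):
    """Metric is undefined for the given inputs (e.g. all-zero weights)."""
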