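"""Exception hierarchy shared across the package."""


class AaeclustError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AaeclustError):
    """An on-disk artifact does not have the expected structure."""


class ValidationError(AaeclustError):
    """Input content violates a documented invariant (negative value, duplicate id, ...)."""


class ShapeError(AaeclustError, ValueError):
    """Array dimensions do not match the operation's contract."""


class TrainingError(AaeclustError):
    """Numerical failure (NaN/Inf loss) during embedder training."""


class DegeneratePartitionError(AaeclustError):
    """A clustering is too degenerate for the requested statistic."""
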