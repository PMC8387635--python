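"""Exception hierarchy shared across the pipeline stages."""


class EmonetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(EmonetError, ValueError):
    """A simulation or rating specification violates its invariants."""


class InvalidBandError(EmonetError, ValueError):
    """A frequency band is empty, inverted, or extends past Nyquist."""


class InvalidMontageError(EmonetError, ValueError):
    """The channel layout cannot support the requested operation."""


class InsufficientDataError(EmonetError, ValueError):
    """A recording is too short for the requested epoching."""


class RankDeficiencyError(EmonetError, ValueError):
    """The sensor gram matrix is singular and no regularization was given."""


class ShapeError(EmonetError, ValueError):
    """Array dimensions do not match between two pipeline objects."""


class InvalidParcellationError(EmonetError, ValueError):
    """A cortical region has no member sources."""


class IntegrityError(EmonetError, ValueError):
    """An input violates a structural contract (e.g. asymmetric FC matrix)."""


class StratificationError(EmonetError, ValueError):
    """A class has too few samples for the requested fold count."""


class MissingDataError(EmonetError, ValueError):
    """A required design cell (scenario/emotion/item stratum) is absent."""


class InfiniteEffectError(EmonetError, ValueError):
    """Zero pooled variance with unequal means: effect size is unbounded."""


class SchemaError(EmonetError, ValueError):
    """A feature table lacks an expected band block or label column."""


class StageError(EmonetError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
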