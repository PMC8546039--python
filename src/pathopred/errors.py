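"""Exception hierarchy shared across the package."""


class PathopredError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PathopredError):
    """A table or config does not match its declared schema."""


class DuplicateVariantError(PathopredError):
    """The same variant key appears twice with conflicting annotations."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"conflicting duplicate variant keys: {self.keys}")


class ConfigurationError(PathopredError):
    """A run or training-set configuration is invalid."""


class DegenerateLabelsError(PathopredError):
    """An evaluation or fit was attempted with a single label class."""


class RebalanceError(PathopredError):
    """Positive/negative weight rebalancing is undefined (a zero total)."""


class StratificationError(PathopredError):
    """Cross-validation folds cannot be stratified as requested."""
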