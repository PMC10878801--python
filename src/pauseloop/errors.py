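"""Exception hierarchy shared across the package."""


class PauseLoopError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PauseLoopError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class InsufficientDataError(PauseLoopError, ValueError):
    """An operation received too little data to produce a defined result."""


class MissingCellError(PauseLoopError, KeyError):
    """A condition x direction cell of the design has no subjects."""

    def __init__(self, metric: str, condition: str, direction: str):
        self.metric = metric
        self.condition = condition
        self.direction = direction
        super().__init__(
            f"no subjects in cell condition={condition}, direction={direction} "
            f"(metric {metric!r})"
        )
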