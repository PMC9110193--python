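"""Exception hierarchy shared across the package."""


class CTPError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CTPError, ValueError):
    """A parameter or spec value is outside its valid range."""


class DimensionError(CTPError, ValueError):
    """Array shapes or time grids do not agree."""


class SingularOperatorError(CTPError, RuntimeError):
    """The convolution operator cannot be inverted (e.g. all-zero AIF)."""


class DivergenceError(CTPError, RuntimeError):
    """An iterative solver produced non-finite iterates."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"non-finite iterate at iteration {iteration}")


class UsageError(CTPError, ValueError):
    """The caller asked for something the inputs cannot support."""
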