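"""Exception hierarchy shared across the package."""


class EchoregError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EchoregError, ValueError):
    """Invalid data passed to an operation (NaNs, bad shapes, bad ranges)."""


class GeometryError(EchoregError, ValueError):
    """Geometric precondition violated (mismatched grids, degenerate points)."""


class ParameterError(EchoregError, ValueError):
    """Invalid parameter value."""


class PipelineError(EchoregError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
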