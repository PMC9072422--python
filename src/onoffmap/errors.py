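"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its documented domain."""


class GenerationError(RuntimeError):
    """The synthetic generator cannot satisfy the requested configuration."""


class DegenerateBaselineError(RuntimeError):
    """A kernel stack has zero norm at delay zero and no signal anywhere."""


class ValidationError(ValueError):
    """A serialized artefact failed schema or invariant validation."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
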