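"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class GenerationError(RuntimeError):
    """Procedural image generation could not satisfy its contract."""
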