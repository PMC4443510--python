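"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violated a documented invariant; the message names the field."""


class PrimerAmbiguityError(ValueError):
    """A PCR primer matched the template at more than one position."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
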