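"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class GenerationError(RuntimeError):
    """Synthetic-cohort generation could not realize the requested effect."""


class StructuralError(ValueError):
    """Inputs are structurally inconsistent (shapes, indexing, bookkeeping)."""


class CohortFormatError(ValueError):
    """A cohort file on disk is malformed; the message names the subject."""
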