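"""Exception hierarchy shared across the package."""


class SlonlineError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SlonlineError):
    """A design spec, observer parameterization, or filter config is invalid."""


class GenerationError(SlonlineError):
    """Sequence constraints could not be satisfied within the retry budget."""


class SchemaError(SlonlineError):
    """A trial/response table is malformed (missing columns, bad values)."""


class EstimationError(SlonlineError):
    """A statistical model could not be estimated (non-convergence, degeneracy)."""


class PipelineError(SlonlineError):
    """A pipeline stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest=None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.manifest = manifest
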