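"""Exception hierarchy shared across the pipeline."""


class PhylonicheError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PhylonicheError, ValueError):
    """A configuration or function parameter is outside its documented range."""


class ValidationError(PhylonicheError, ValueError):
    """An input file or table violates its contract (names the offending cell)."""


class DegenerateGeometryError(PhylonicheError, ValueError):
    """A geometric computation received rank-deficient or undersized input.

    Raised instead of silently jittering points: perturbation would corrupt
    null distributions built from hull volumes.
    """


class StageError(PhylonicheError, RuntimeError):
    """A pipeline stage failed; carries the stage name and a reproduction hint."""

    def __init__(self, stage: str, message: str, repro: str | None = None):
        self.stage = stage
        self.repro = repro
        hint = f" (reproduce with: {repro})" if repro else ""
        super().__init__(f"stage '{stage}' failed: {message}{hint}")
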