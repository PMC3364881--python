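"""Exception hierarchy for dscamscan."""


class DscamscanError(Exception):
    """Base class for all package errors."""


class FormatError(DscamscanError):
    """Malformed input file (ragged alignment, bad Newick, bad FASTA...)."""


class ValidationError(DscamscanError):
    """Input violates a documented invariant."""


class BuildError(DscamscanError):
    """Profile construction impossible (e.g. all columns gapped)."""


class CalibrationError(DscamscanError):
    """Gumbel calibration failed (degenerate score distribution)."""


class UncalibratedError(DscamscanError):
    """E-value requested from a profile with no calibration parameters."""


class PlacementError(DscamscanError):
    """A planted synthetic feature does not fit or overlaps another."""


class PipelineError(DscamscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
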