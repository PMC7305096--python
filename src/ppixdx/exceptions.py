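"""Exception hierarchy.

Split so a shell caller can map failures to distinct exit codes:
configuration/validation problems, data problems (e.g. a single-class
score table), and file I/O problems.
"""


class PpixdxError(Exception):
    """Base class for all package errors."""


class ValidationError(PpixdxError, ValueError):
    """A domain invariant or precondition is violated."""


class UnknownExcitationError(ValidationError):
    """Requested excitation wavelength absent from a fluorophore's efficiency map."""


class MissingBandError(ValidationError):
    """A required (band, phase) image is absent from a node record."""


class MaskTooSmallError(ValidationError):
    """Mask erosion emptied the analysis region; the node is too small for the margin."""


class FluenceShortfallError(ValidationError):
    """Post-irradiation acquisition does not carry the required extra fluence."""


class DataError(PpixdxError, ValueError):
    """The data are structurally valid but statistically unusable."""


class SingleClassError(DataError):
    """Both class labels are required (ROC / calibration) but only one is present."""


class UndefinedMetricError(DataError):
    """A diagnostic metric's denominator class is empty."""


class NodeIOError(PpixdxError, OSError):
    """Reading or writing a node acquisition failed."""


class PipelineError(PpixdxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending node."""

    def __init__(self, stage: str, node_id: str | None, message: str):
        self.stage = stage
        self.node_id = node_id
        suffix = f" (node {node_id})" if node_id is not None else ""
        super().__init__(f"stage '{stage}'{suffix}: {message}")
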