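"""Exception hierarchy shared by all unfoldmap modules."""


class UnfoldmapError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(UnfoldmapError):
    """A PDB record could not be parsed; the message names the offending line."""


class TopologyError(UnfoldmapError):
    """Frames or structures disagree on atom count/ordering."""


class ConfigError(UnfoldmapError):
    """Invalid configuration: bad selection, missing charges/radii, bad spec."""


class ShapeError(UnfoldmapError):
    """Tabular data is ragged or a matrix has the wrong shape/symmetry."""


class RankError(UnfoldmapError):
    """Requested more components than the data rank supports."""


class UndefinedMetricError(UnfoldmapError):
    """A metric is undefined for this input (e.g. empty contact set)."""


class DegenerateDataError(UnfoldmapError):
    """Input has zero variance where spread is required."""


class NoTransitionError(UnfoldmapError):
    """The folded/unfolded neighbor fractions never cross."""


class CalibrationError(UnfoldmapError):
    """No frames available in the calibration window."""


class PipelineStageError(UnfoldmapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
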