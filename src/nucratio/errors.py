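"""Exception hierarchy for the nucratio pipeline.

Every stage raises a subclass of :class:`NucratioError` so callers can
distinguish pipeline failures from programming errors.
"""


class NucratioError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(NucratioError, ValueError):
    """Invalid parameter value (bad enum, negative count, inverted bounds...)."""


class ValidationError(NucratioError, ValueError):
    """Input data violates a precondition (empty list, unequal lengths...)."""


class BoundsError(NucratioError, ValueError):
    """Geometry does not fit inside the declared stack."""


class GenerationError(NucratioError, RuntimeError):
    """Synthetic rendering failed (e.g. unresolvable nucleus collisions)."""


class LabelNotFoundError(NucratioError, KeyError):
    """A requested nucleus label is absent from the mask."""


class EmptyMeasurementError(NucratioError, ValueError):
    """A measurement region contains zero voxels."""


class EmptyRegionError(NucratioError, ValueError):
    """A cytoplasm region is empty (outline swallowed by the nucleus mask)."""


class UndefinedRatioError(NucratioError, ZeroDivisionError):
    """A ratio denominator is zero; reported as missing, never as infinity."""


class InsufficientReferenceError(NucratioError, ValueError):
    """Fewer internal-reference (DA) cells than the minimum required."""


class GroupingError(NucratioError, ValueError):
    """Records that must share a grouping key (embryo id) do not."""


class AlignmentError(NucratioError, ValueError):
    """Frame-indexed inputs (grids, masks) are misaligned with a track."""


class FormatError(NucratioError, ValueError):
    """A file lacks required metadata (axes, voxel size) and no override given."""


class ChannelError(NucratioError, ValueError):
    """A stack does not provide the two requested channels."""


class PipelineStageError(NucratioError, RuntimeError):
    """A pipeline stage failed; message names the stage and offending input."""
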