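"""Exception hierarchy shared by all pipeline stages."""


class StressVbmError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(StressVbmError):
    """A generator specification is infeasible or violates its invariants."""


class MalformedInputError(StressVbmError):
    """An input table or series violates its structural contract."""


class ContractViolationError(StressVbmError):
    """An operation was called outside its precondition."""


class DegenerateVarianceError(StressVbmError):
    """A statistic is undefined because the data carry no spread."""


class MappingError(StressVbmError):
    """A sample refers to a region label absent from the atlas."""


class EmptyMaskError(StressVbmError):
    """The analysis mask contains no voxels."""


class GeometryError(StressVbmError):
    """Volume grids or voxel sizes are inconsistent."""


class DesignError(StressVbmError):
    """The design matrix is rank deficient or mismatched to the data."""


class InsufficientGroupError(StressVbmError):
    """A group has too few subjects for the requested model."""


class ConfigurationError(StressVbmError):
    """A configuration file or threshold map is invalid or incomplete."""


class PipelineError(StressVbmError):
    """A pipeline stage failed; the stage name is included in the message."""
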