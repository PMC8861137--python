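"""Exception hierarchy for the CT-OAM pipeline."""


class CTOAMError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CTOAMError):
    """A file is unreadable or lacks required metadata (e.g. voxel spacing)."""


class ParameterError(CTOAMError):
    """A caller-supplied parameter violates its contract."""


class EmptyMaskError(CTOAMError):
    """A mask or plate footprint contains no voxels/pixels."""


class RangeError(CTOAMError):
    """A value cannot be represented in the target encoding."""


class DesignError(CTOAMError):
    """A statistical design is degenerate (e.g. a factor with one level)."""
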