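"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A configuration file or parameter set is invalid (unknown key, missing field)."""


class GeometryError(ValueError):
    """A geometric operation cannot be carried out on this grid (object out of bounds)."""


class SegmentationError(RuntimeError):
    """Segmentation produced an unusable result (e.g. empty foreground)."""


class AmbiguousAxisError(ValueError):
    """The principal axis is not well defined (near-isotropic mask)."""


class AlignmentStateError(RuntimeError):
    """An operation requiring an axis-aligned stack received an unaligned one."""
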