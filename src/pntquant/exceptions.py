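"""Package-wide exception types."""


class ValidationError(ValueError):
    """A parameter object violates one of its documented invariants."""


class GeometryError(ValueError):
    """The requested imaging geometry cannot contain the simulated anatomy."""


class SegmentationError(RuntimeError):
    """Segmentation could not produce a usable result."""


class DegenerateContrastError(SegmentationError):
    """Blood and myocardium intensities are not separable."""


class DegenerateStatisticsError(ValueError):
    """A statistical routine received data with no usable variance."""
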