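"""Exception hierarchy for comflow.

All comflow-specific failures derive from :class:`ComflowError` so callers
can catch the package's errors with a single ``except`` clause.
"""


class ComflowError(Exception):
    """Base class for all comflow errors."""


class InvalidGeometryError(ComflowError):
    """Phantom or contour geometry that cannot be constructed."""


class InvalidMotionError(ComflowError):
    """Prescribed phantom motion would make the wall self-overlap."""


class InvalidSpecError(ComflowError):
    """Pyramid or solver specification outside its valid domain."""


class InvalidContourError(ComflowError):
    """Wall contour violating ordering/landmark requirements."""


class DegenerateGeometryError(ComflowError):
    """Coincident vertices or otherwise degenerate local geometry."""


class TrackingLostError(ComflowError):
    """A segment ROI was advected to the empty set.

    Carries the segment label and the frame index at which tracking failed.
    """

    def __init__(self, segment_label, frame_index):
        self.segment_label = segment_label
        self.frame_index = frame_index
        super().__init__(
            f"ROI of segment {segment_label!r} became empty at frame {frame_index}"
        )


class ParseError(ComflowError):
    """Malformed input file."""
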