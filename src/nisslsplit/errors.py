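"""Exception hierarchy for the nisslsplit pipeline."""


class NisslSplitError(Exception):
    """Base class for all package errors."""


class ValidationError(NisslSplitError, ValueError):
    """A parameter or input violates a documented precondition."""


class FormatError(NisslSplitError, ValueError):
    """An on-disk volume is malformed (missing, unsorted or mismatched slices)."""


class RangeError(NisslSplitError, ValueError):
    """A coordinate or block lies outside the volume extent."""


class TopologyError(NisslSplitError, ValueError):
    """A region mask lacks the topology an operation requires."""


class PlacementError(NisslSplitError, RuntimeError):
    """Phantom object placement failed after bounded retries."""
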