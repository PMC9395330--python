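"""Exception hierarchy for reeftrack."""


class ReeftrackError(Exception):
    """Base class for all reeftrack errors."""


class FormatError(ReeftrackError, ValueError):
    """A file did not conform to the expected dialect."""


class CalibrationError(ReeftrackError, ValueError):
    """HPE calibration could not be performed."""


class GridError(ReeftrackError, ValueError):
    """A raster/voxel grid is inconsistent with the request."""


class TwilightUndefinedError(ReeftrackError, ValueError):
    """Sun never reaches the requested altitude on this date/latitude."""
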