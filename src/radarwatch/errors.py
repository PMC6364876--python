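"""Exception types shared across the package."""


class RadarwatchError(Exception):
    """Base class for package errors."""


class SchemaError(RadarwatchError):
    """A required input column is missing or unmappable."""


class DegenerateTrackError(RadarwatchError):
    """Track too short for the requested operation (e.g. single fix)."""


class InsufficientDataError(RadarwatchError):
    """Not enough observations to compute the quantity."""


class NotApplicableError(RadarwatchError):
    """Operation requires radar scans but the device never scanned.

    Distinct from "zero encounters": a GPS-only track carries no information
    about vessel presence, so encounter rates are undefined, not zero.
    """


class UndefinedProportionError(RadarwatchError):
    """A proportion was requested over an empty selection of fixes."""
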