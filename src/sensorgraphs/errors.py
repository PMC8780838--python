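"""Exception hierarchy used across the package."""


class SensorGraphError(Exception):
    """Base class for all package-specific errors."""


class EventLogParseError(SensorGraphError):
    """A raw input file could not be parsed (names the offending row)."""


class ContentError(SensorGraphError):
    """Inputs parsed but their content is inconsistent (labels, ids, shapes)."""


class TopologySchemaError(SensorGraphError):
    """A flat-topology JSON file violates its schema."""


class FormatError(SensorGraphError):
    """A matrix or report file has an invalid layout."""


class ParameterError(SensorGraphError):
    """An argument is outside its admissible range."""


class InsufficientDataError(SensorGraphError):
    """Too few observations for the requested computation."""


class DegenerateBaselineError(SensorGraphError):
    """The weighted baseline total is zero, so a percent difference is undefined."""


class FitError(SensorGraphError):
    """A least-squares fit is not identifiable (too few or degenerate abscissae)."""
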