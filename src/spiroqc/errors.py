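"""Exception hierarchy for spiroqc."""


class SpiroQCError(Exception):
    """Base class for all spiroqc errors."""


class SchemaError(SpiroQCError):
    """A session document violates the documented schema."""


class ParseError(SchemaError):
    """A session file could not be parsed; message names the offending field."""


class InputError(SpiroQCError):
    """Inconsistent or invalid inputs to an operation."""


class DegenerateManeuverError(SpiroQCError):
    """A maneuver carries no usable expiratory signal (e.g. all-zero volume)."""


class SimulationSpecError(SpiroQCError):
    """A synthetic maneuver/cohort specification is invalid."""
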