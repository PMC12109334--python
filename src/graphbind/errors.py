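"""Exception hierarchy for graphbind.

Every failure mode named by the pipeline contracts (parse errors, valence
violations, degenerate geometry, empty pockets, insufficient data) maps to a
distinct exception so callers can filter complexes instead of crashing runs.
"""


class GraphBindError(Exception):
    """Base class for all graphbind errors."""


class ParseError(GraphBindError):
    """A structure file could not be parsed; message names the offending line."""


class EmptyStructureError(ParseError):
    """A structure file contained zero atoms."""


class SanitizationError(GraphBindError):
    """Chemical validity check failed; message identifies the atom."""


class DegenerateSiteError(GraphBindError):
    """Two Voronoi sites coincide."""


class ChargeAssignmentError(GraphBindError):
    """Partial charges missing or could not be computed."""


class DimensionError(GraphBindError):
    """Feature matrix width disagrees with the schema."""


class EmptyPocketError(GraphBindError):
    """No protein atom survived the distance cutoff."""


class SchemaError(GraphBindError):
    """Unknown feature group name."""


class InsufficientDataError(GraphBindError):
    """Too few samples for the requested fit or split."""


class DivergenceError(GraphBindError):
    """Training loss became non-finite."""
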