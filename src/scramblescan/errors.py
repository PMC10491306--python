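"""Exception hierarchy for scramblescan.

All package-specific failures derive from :class:`ScrambleScanError` so callers
can catch one base class at pipeline boundaries.
"""


class ScrambleScanError(Exception):
    """Base class for all scramblescan errors."""


class TopologyError(ScrambleScanError):
    """Unreadable or inconsistent topology/trajectory input (e.g. atom-count
    mismatch between a topology and a trajectory file)."""


class SelectionError(ScrambleScanError):
    """A residue/bead selection matched nothing or a residue is malformed."""


class GeometryError(ScrambleScanError):
    """Degenerate geometry: zero-length orientation vectors, monolayers,
    bilayers wrapped across the z boundary, ..."""


class AnalysisError(ScrambleScanError):
    """An analysis precondition is violated (trajectory too short, empty
    selection, ambiguous density profile, ...)."""


class SpecError(ScrambleScanError):
    """A synthetic-bilayer specification violates its invariants."""
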