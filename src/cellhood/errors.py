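"""Exception hierarchy for cellhood.

All package-specific failures derive from :class:`CellhoodError` so callers
can catch one base class at pipeline boundaries.
"""


class CellhoodError(Exception):
    """Base class for all cellhood errors."""


class SchemaError(CellhoodError):
    """An input table violates its declared schema (missing columns,
    duplicate cell ids, wrong dtypes)."""


class ParseError(CellhoodError):
    """A row of an input table could not be parsed; the message names the
    offending file line(s)."""


class ConfigurationError(CellhoodError):
    """A rule set, simulation config or QC request references something
    that does not exist or is out of range."""


class FrameError(CellhoodError):
    """Cells from more than one ROI/coordinate frame were passed to an
    operation that assumes a single frame."""


class StateError(CellhoodError):
    """An operation was called before a prerequisite step (e.g. lipid
    metrics before lipid flags are assigned)."""


class InsufficientDataError(CellhoodError):
    """Too few observations for the requested computation (empty gate
    input, groups of size < 2, fewer than 2 segments)."""


class DegenerateDataError(CellhoodError):
    """The data admit no meaningful answer (all intensities tied at the
    gate, zero variance in both t-test groups)."""
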