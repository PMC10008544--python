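"""Exception hierarchy shared across the package.

Everything derives from :class:`FlexrinError` so callers can catch the
package's failures without masking programming errors.
"""


class FlexrinError(Exception):
    """Base class for all package errors."""


class FormatError(FlexrinError, ValueError):
    """A file could not be parsed (PDB line, confidence JSON, CSV)."""


class TopologyError(FlexrinError, ValueError):
    """Frames of one ensemble do not share residue/atom topology."""


class ParameterError(FlexrinError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(FlexrinError, ValueError):
    """Degenerate geometry: too few points, collinear sets, missing atoms."""


class MismatchError(FlexrinError, ValueError):
    """Two per-residue tracks or matrices do not share keys/dimensions."""
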