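"""Exception hierarchy for ugdyn."""


class UgdynError(Exception):
    """Base class for all ugdyn errors."""


class ParseError(UgdynError):
    """A structure or trajectory file could not be parsed."""


class FormatError(UgdynError):
    """An unsupported or malformed file format was requested."""


class SelectionError(UgdynError):
    """An atom/residue selection matched nothing that was required."""


class MissingResidueError(SelectionError):
    """A residue required by an operation is not resolved in the model."""


class AtomCountMismatchError(UgdynError):
    """Trajectory frame atom count does not match its topology."""


class DegenerateGeometryError(UgdynError):
    """Coordinates are degenerate for the requested geometric operation
    (coincident centers, collinear point sets, <3 atoms for superposition)."""
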