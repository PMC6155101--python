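"""Exception hierarchy.

Every failure mode that callers may want to trap separately gets its own
class; all inherit from :class:`BarrelJointError` so a pipeline can catch
one base type per structure and keep going.
"""


class BarrelJointError(Exception):
    """Base class for all errors raised by this package."""


class MissingFileError(BarrelJointError, FileNotFoundError):
    """An input file does not exist or is unreadable."""


class UnknownChainError(BarrelJointError, KeyError):
    """The requested chain is not present in the selected model."""


class NoCAlphaError(BarrelJointError):
    """The selected chain contains no C-alpha atoms at all."""


class ParseError(BarrelJointError, ValueError):
    """An annotation file (STRIDE output, segment table, TM table) has a
    malformed line; the message names the offending line/row number."""


class AnnotationError(BarrelJointError, ValueError):
    """Strand ranges overlap or otherwise cannot form a valid
    strand/loop alternation."""


class TooFewStrandsError(AnnotationError):
    """Fewer than two strands remain after validation/merging, so no
    dihedral can be defined."""


class MissingTerminusError(AnnotationError):
    """A strand's first or last residue has no C-alpha in the trace."""


class AmbiguousBoundaryError(AnnotationError):
    """A TM residue range intersects zero or more than one strand."""


class DegenerateGeometryError(BarrelJointError, ValueError):
    """A torsion quadruple has coincident or collinear points."""


class SpecError(BarrelJointError, ValueError):
    """A synthetic-generator specification violates its invariants."""


class ConfigError(BarrelJointError, ValueError):
    """An analysis parameter is invalid (e.g. histogram width that does
    not divide 360)."""
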