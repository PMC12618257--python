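"""Exception hierarchy.

Every error raised by the package derives from :class:`ArpGeomError`, so
callers (and the CLI) can catch one type.  The leaf classes mirror the
failure modes of the pipeline: parsing, subunit mapping, anchor resolution,
degenerate geometry, and fixture/parameter validation.
"""


class ArpGeomError(Exception):
    """Base class for all package errors."""


class ParseError(ArpGeomError):
    """A coordinate file could not be parsed."""


class FormatError(ArpGeomError):
    """Unknown or unsupported coordinate format."""


class MappingError(ArpGeomError):
    """A logical subunit cannot be resolved through the SubunitMap."""


class AnchorMissingError(ArpGeomError):
    """A named anchor residue/atom is absent from the mapped chain."""


class AnchorIdentityError(ArpGeomError):
    """The residue at an anchor position has an unexpected identity."""


class DegenerateGeometryError(ArpGeomError):
    """Collinear/coincident input where a well-defined answer needs more."""


class EmptySelectionError(ArpGeomError):
    """An atom selection that must be non-empty is empty."""


class PairingError(ArpGeomError):
    """Two atom lists cannot be paired for superposition."""


class MassTableError(ArpGeomError):
    """An element is missing from the atomic mass table."""


class RadiiError(ArpGeomError):
    """An element is missing from the van der Waals radii set."""


class SequenceError(ArpGeomError):
    """A protein sequence contains an unknown residue letter or is empty."""


class DisjointnessError(ArpGeomError):
    """Two interface sides share a subunit."""


class ParameterError(ArpGeomError):
    """A fixture or run parameter is out of range."""


class ConfigError(ArpGeomError):
    """A run configuration file is missing or inconsistent."""


class FetchError(ArpGeomError):
    """A remote structure could not be downloaded."""
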