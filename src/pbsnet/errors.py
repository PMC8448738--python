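"""Exception hierarchy for pbsnet.

Every error raised by the library derives from :class:`PbsnetError`, so
callers (including the CLI) can catch a single base class.
"""


class PbsnetError(Exception):
    """Base class for all pbsnet errors."""


class StructureIOError(PbsnetError):
    """Unreadable file, unknown format, or a file that parses to nothing."""


class EmptyModelError(StructureIOError):
    """A coordinate file that yields zero atoms."""


class FormatError(StructureIOError):
    """Unrecognized or unsupported coordinate format."""


class AnnotationError(PbsnetError):
    """Problems with subunit role/region annotation."""


class AmbiguousRoleError(AnnotationError):
    """Two annotation rules assign different roles to the same chain."""


class AnnotationRequiredError(AnnotationError):
    """An operation that needs role/region annotation got an unannotated model."""


class NomenclatureError(PbsnetError):
    """Ligand atom names do not follow bilin ring nomenclature."""


class MetricUndefinedError(PbsnetError):
    """A distance metric has an empty atom selection on one of its operands."""


class EmptySelectionError(PbsnetError):
    """An atom selection (e.g. side-chain atoms of Gly) is empty."""


class DegenerateGeometryError(PbsnetError):
    """Too few or collinear points for a geometric computation."""


class InvalidPlacementError(PbsnetError):
    """A rigid-body placement whose rotation is not a proper rotation."""


class FixtureSpecError(PbsnetError):
    """A synthetic-fixture specification that is geometrically infeasible."""


class UnknownNodeError(PbsnetError):
    """A graph query referencing a chromophore id absent from the network."""


class ConfigurationError(PbsnetError):
    """An analysis configuration that cannot produce a meaningful result."""
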