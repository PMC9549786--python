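"""Exception hierarchy for pocketsphere.

All data-level failures derive from :class:`PocketsphereError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class PocketsphereError(Exception):
    """Base class for all pocketsphere data errors."""


class FormatError(PocketsphereError):
    """Structure file content could not be parsed."""


class EmptyStructureError(PocketsphereError):
    """Parsed file contains no atomic coordinates."""


class InvalidLigandError(PocketsphereError):
    """Ligand instance is unusable (e.g. no atoms, no heavy atoms)."""


class DegenerateSphereError(PocketsphereError):
    """Sphere construction produced an empty protein shell."""


class DegenerateSuperpositionError(PocketsphereError):
    """Too few or collinear points for a rigid superposition."""


class AlignmentInfeasibleError(PocketsphereError):
    """Not enough representative points to attempt structural alignment."""


class InvalidCriteriaError(PocketsphereError):
    """Contradictory or incomplete library preselection criteria."""


class InvalidInputError(PocketsphereError):
    """Generic invalid argument (empty sequence, bad range, ...)."""


class EmptyReferenceError(PocketsphereError):
    """A unified-binding-site reference has no contact residues."""


class GenerationError(PocketsphereError):
    """Synthetic fixture parameters are geometrically infeasible."""
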