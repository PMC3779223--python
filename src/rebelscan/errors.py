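"""Exception hierarchy for rebelscan.

Every user-facing failure mode has a named exception so callers (and the
CLI) can distinguish config, input and computation errors.
"""


class RebelscanError(Exception):
    """Base class for all rebelscan errors."""


# --- structure / alignment input errors -----------------------------------

class PDBInputError(RebelscanError):
    """Base class for PDB reading failures."""


class PDBFileMissingError(PDBInputError, FileNotFoundError):
    """The PDB file does not exist."""


class NoCalphaAtomsError(PDBInputError):
    """The PDB file contains no ATOM record with atom name CA."""


class PDBFieldError(PDBInputError):
    """A coordinate (or other mandatory) field could not be parsed."""


class AlignmentFormatError(RebelscanError):
    """Malformed gapped-FASTA alignment (unequal rows, duplicate headers,
    empty file, or a gap character other than '-')."""


class AlignmentMismatchError(RebelscanError):
    """Alignment member ids do not match the supplied structures."""


# --- geometry errors -------------------------------------------------------

class DegenerateGeometryError(RebelscanError):
    """Point set has rank < 2 (collinear or coincident points)."""


class TooFewPointsError(RebelscanError):
    """Fewer matched points than the operation requires."""


class NoCoreColumnsError(RebelscanError):
    """Alignment has no column that is ungapped in every member."""


# --- ontology errors -------------------------------------------------------

class OntologyError(RebelscanError):
    """Base class for GO ontology failures."""


class OntologyCycleError(OntologyError):
    """The parsed term graph contains a cycle (not a DAG)."""


class UndefinedTermError(OntologyError):
    """A term id was referenced but never defined (or queried but absent)."""


# --- pipeline errors -------------------------------------------------------

class ConfigError(RebelscanError):
    """Invalid pipeline configuration."""
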