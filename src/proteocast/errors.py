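"""Named exception types raised on malformed user input.

Every error a caller can trigger with bad input derives from
:class:`ProteocastInputError`, so pipeline drivers can distinguish user
mistakes (exit with a message) from genuine bugs (let the traceback fly).
"""


class ProteocastInputError(ValueError):
    """Base class for all input-validation failures."""


class EmptyMsaError(ProteocastInputError):
    """The alignment file contains no sequence records."""


class GappedQueryError(ProteocastInputError):
    """The first (query) record still contains gaps after normalisation."""


class RaggedAlignmentError(ProteocastInputError):
    """Rows have inconsistent lengths after dialect normalisation."""


class UnknownDialectError(ProteocastInputError):
    """The requested MSA dialect is not recognised, or characters in the
    file are incompatible with the declared dialect."""


class ScoreMatrixError(ProteocastInputError):
    """A score-matrix CSV is malformed or inconsistent with the query."""


class InsufficientScoresError(ProteocastInputError):
    """Too few finite scores to fit a three-component mixture."""


class GmmDegenerateError(ProteocastInputError):
    """EM collapsed (component variance below floor) on every restart."""


class SegmentationInputError(ProteocastInputError):
    """Non-finite profile values, non-positive weights, or length mismatch."""


class StructureError(ProteocastInputError):
    """PDB parsing failed, the chain is missing, or no standard residues."""


class MutationFileError(ProteocastInputError):
    """Annotated-mutation CSV is malformed or disagrees with the query."""


class SyntheticSpecError(ProteocastInputError):
    """A synthetic-fixture specification is invalid (e.g. overlapping motifs)."""
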