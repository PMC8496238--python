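"""Exception hierarchy.

Every failure mode a caller can act on gets its own class; the CLI maps
them to documented exit codes.
"""


class TagbackError(Exception):
    """Base class for all package errors."""


class MotifParseError(TagbackError, ValueError):
    """Malformed target-motif string; message names the offending character and index."""


class FormatError(TagbackError, ValueError):
    """Malformed FASTA/GFF3/feature-literal input."""


class IntegrationError(TagbackError):
    """Donor homology arm missing, duplicated, or out of order during simulated HDR."""


class FeatureNotEditableError(TagbackError):
    """No QC-passing nuclease target inside the maximally expanded feature."""


class UniqueInsertError(TagbackError):
    """Rejection sampling for a genome-unique landing pad exhausted its attempts."""


class ArmError(TagbackError):
    """Homology arm off the contig end or not unique in the genome."""


class PrimerRoleError(TagbackError):
    """A mandatory primer role has no candidates."""


class CFDTableError(TagbackError):
    """CFD penalty table missing or lacking a required entry."""
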