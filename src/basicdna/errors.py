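"""Exception hierarchy.

Every error raised by the package derives from :class:`BasicDnaError` so
callers can catch domain failures without masking programming errors.
"""

from __future__ import annotations


class BasicDnaError(Exception):
    """Base class for all basicdna errors."""


class InvalidSequenceError(BasicDnaError, ValueError):
    """Sequence contains characters outside the DNA alphabet."""


class AmbiguousSequenceError(InvalidSequenceError):
    """Sequence contains IUPAC ambiguity codes (N, R, Y, ...).

    Distinct from :class:`InvalidSequenceError` so callers can tell
    "this is DNA but degenerate" apart from "this is not DNA at all".
    """


class MissingFlankError(BasicDnaError, ValueError):
    """A sequence declared storage-format lacks the iP prefix or iS suffix."""


class FeatureBoundsError(BasicDnaError, ValueError):
    """Feature coordinates fall outside the parent sequence."""


class MissingBoundaryError(BasicDnaError, ValueError):
    """Assembly-to-part conversion requires exactly one LMP and one LMS linker."""


class MultipleBoundaryError(BasicDnaError, ValueError):
    """More than one LMP (or LMS) boundary linker present."""


class AssemblyValidationError(BasicDnaError):
    """An assembly failed validation; carries the offending issues."""

    def __init__(self, issues, message: str | None = None):
        self.issues = list(issues)
        if message is None:
            message = "; ".join(f"{i.code}: {i.message}" for i in self.issues)
        super().__init__(message)


class ParameterError(BasicDnaError, ValueError):
    """A numeric or configuration parameter is out of range."""


class PrimerDesignError(BasicDnaError):
    """No terminal annealing region satisfies the melting-temperature window."""


class ParseError(BasicDnaError, ValueError):
    """A sequence file could not be parsed."""


class EmptyFileError(ParseError):
    """A sequence stream contained no records."""


class FormatCapabilityError(BasicDnaError, ValueError):
    """Requested output format cannot represent the record (e.g. circular FASTA)."""


class BuildConsistencyError(BasicDnaError):
    """A build plan is internally inconsistent (id collisions, dangling refs)."""


class SchemaError(BasicDnaError, ValueError):
    """A build document violates the BasicBuild schema; message carries the path."""


class DanglingKeyError(SchemaError):
    """A build document references an absent unique-part/linker/clip key."""


class VersionMismatchError(SchemaError):
    """Unknown BasicBuild schema version."""


class PlateOverflowError(BasicDnaError):
    """More source or destination wells required than the plate provides."""


class QuantizationError(BasicDnaError, ValueError):
    """A transfer volume is not an integer multiple of the droplet quantum."""


class RecipeInfeasibleError(BasicDnaError):
    """Clip volumes exceed the total assembly-reaction volume."""


class UnknownCollectionError(BasicDnaError, KeyError):
    """Requested part/linker collection name or version is not registered."""
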