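"""Exception hierarchy shared across the package."""


class PhylOriginsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhylOriginsError, ValueError):
    """Invalid argument or malformed input data."""


class AlignmentError(ValidationError):
    """Sequences violate alignment invariants (lengths, ids, characters)."""


class EmptyResultError(PhylOriginsError):
    """A filter or subset operation produced an empty alignment."""


class NewickError(ValidationError):
    """Malformed Newick text or invalid tree structure."""


class LabelError(ValidationError):
    """A taxon label map does not cover the leaves of a tree."""
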