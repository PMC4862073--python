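"""Exception hierarchy.

Every error raised on bad user input derives from :class:`HoxatlasError`
so callers (and the CLI) can distinguish usage errors from bugs.
"""


class HoxatlasError(Exception):
    """Base class for all package errors."""


class ParseError(HoxatlasError):
    """Malformed input file (FASTA/GFF3/TSV)."""


class BoundsError(HoxatlasError):
    """A feature interval falls outside its scaffold."""


class LinkageError(HoxatlasError):
    """A child feature has no resolvable parent (e.g. orphan mRNA)."""


class VocabularyError(HoxatlasError):
    """A label is not in the fixed Hox class vocabulary."""


class GeneLookupError(HoxatlasError):
    """A referenced gene id does not exist in the annotation."""


class ParameterError(HoxatlasError):
    """An operation parameter is out of its valid range."""


class AlphabetError(HoxatlasError):
    """A sequence contains a symbol outside the scoring alphabet."""


class CapacityError(HoxatlasError):
    """A synthetic-genome spec does not fit in the requested genome size."""


class PlacementError(HoxatlasError):
    """A planted feature would overlap an existing feature."""


class LocationError(HoxatlasError):
    """A mature miRNA sequence cannot be located in a candidate."""
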