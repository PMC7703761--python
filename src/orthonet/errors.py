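"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`OrthonetError`
so the CLI can map them onto stable exit codes.
"""


class OrthonetError(Exception):
    """Base class for all orthonet errors."""


class FormatError(OrthonetError):
    """A file does not conform to its declared format (bad column count,
    non-numeric score, empty sequence, duplicate identifier, ...)."""


class IntegrityError(OrthonetError):
    """An internal invariant was violated (e.g. a non one-to-one ortholog
    map reaching edge transfer)."""


class EmptyResultError(OrthonetError):
    """A computation has no usable input or output (no orthologs, no
    qualifying gold-standard term, no guide gene in the network, ...)."""


class DegenerateInputError(OrthonetError):
    """Statistical input that admits no answer (all paired differences
    zero, all candidates positive, ...)."""
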