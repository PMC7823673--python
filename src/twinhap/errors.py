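"""Exception hierarchy.

All package errors derive from :class:`TwinhapError` so callers (and the CLI)
can distinguish validation problems (exit code 2) from I/O problems (exit
code 3).
"""


class TwinhapError(Exception):
    """Base class for all twinhap errors."""


class FormatError(TwinhapError):
    """A table is structurally malformed (missing column, bad cell type)."""


class ValidationError(TwinhapError):
    """Structurally valid input violates a domain invariant."""


class DegenerateLocusError(ValidationError):
    """A locus cannot be used (zero depth, empty allele set)."""
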