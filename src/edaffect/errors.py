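"""Exception hierarchy used across the package.

All errors derive from :class:`EdaffectError` so callers can catch one base.
Parsing/validation problems raise :class:`FormatError` (a ``ValueError``),
contract violations on otherwise well-formed inputs raise
:class:`ValidationError`.
"""


class EdaffectError(Exception):
    """Base class for all package errors."""


class FormatError(EdaffectError, ValueError):
    """A file or table does not follow the expected dialect."""


class ValidationError(EdaffectError, ValueError):
    """An in-memory object violates a domain invariant or precondition."""


class AlignmentError(EdaffectError, ValueError):
    """Two participant-indexed collections do not cover the same ids."""


class EmptySelectionError(EdaffectError, ValueError):
    """A feature filter rejected every feature."""


class DegeneracyError(EdaffectError, ValueError):
    """Input has too little structure for the requested operation."""
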