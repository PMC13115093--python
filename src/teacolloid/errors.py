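"""Exception hierarchy shared across the package.

``ValidationError`` and its siblings mark bad *input* (exit code 2 at the
CLI); anything else propagating out of the library is an internal error
(exit code 1).
"""


class TeacolloidError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TeacolloidError):
    """A table is missing a required column or has an unexpected layout."""


class ParseError(TeacolloidError):
    """A cell could not be converted to the expected type."""


class ValidationError(TeacolloidError):
    """Values parsed fine but violate a domain invariant."""


class DesignError(TeacolloidError):
    """A synthetic-data design is internally inconsistent."""
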