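"""Exception hierarchy.

``ConfigError`` covers bad parameters or run configuration, ``FormatError``
covers unparseable input files, and ``ValidationError`` covers inputs that
parse but violate a documented contract (e.g. an exon outside its gene span).
The CLI maps these to distinct exit codes.
"""


class BsmethError(Exception):
    """Base class for all package errors."""


class ConfigError(BsmethError):
    """Invalid parameter value or run configuration."""


class FormatError(BsmethError):
    """Malformed input file (parse-level failure)."""


class ValidationError(BsmethError):
    """Well-formed input that violates a documented invariant."""
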