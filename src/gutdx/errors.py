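"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (2 usage, 3 input format,
4 model/profile mismatch).
"""


class GutdxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GutdxError):
    """Malformed input file (ragged rows, duplicate ids, bad cells, ...)."""


class MismatchError(GutdxError):
    """Model bundle and query profile disagree (data type, feature rank)."""
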