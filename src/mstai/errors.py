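"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit
code 2), ``ReadWriteError`` covers file I/O failures (exit code 3), and
``ExclusionError`` signals an image with too little usable normal skin to
estimate a color from — the same category of sample a human annotator
would set aside rather than label.
"""

from __future__ import annotations


class MstAiError(Exception):
    """Base class for all package errors."""


class ValidationError(MstAiError, ValueError):
    """An input violates a documented precondition; the message names the field."""


class ReadWriteError(MstAiError, OSError):
    """A file could not be read or written; the message names the path."""


class ExclusionError(MstAiError):
    """The image has insufficient normal-skin area for color estimation."""

    def __init__(self, reason: str = "excluded: insufficient skin area"):
        super().__init__(reason)
        self.reason = reason
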