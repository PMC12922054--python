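"""Exception hierarchy.

``DataError`` marks problems with user-supplied inputs (bad files, labels,
shapes); everything else raised by the package is a plain ``MicrogameError``.
The CLI maps ``DataError`` to exit code 2 and other failures to 3.
"""


class MicrogameError(Exception):
    """Base class for all errors raised by microgame."""


class DataError(MicrogameError, ValueError):
    """Invalid input data: malformed files, duplicate identifiers,
    missing or non-numeric cells, incomplete or degenerate group labels."""
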