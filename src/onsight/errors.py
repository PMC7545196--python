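"""Exception hierarchy shared across the package.

Validation failures (bad geometry, malformed inputs, parameters out of
range) raise :class:`ValidationError`; failures to locate the ON/ONS
contour pair raise :class:`SelectionError`. The CLI maps ValidationError
to exit code 2 and I/O problems to exit code 3.
"""


class OnsightError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OnsightError, ValueError):
    """Input or parameter fails a documented precondition."""


class SelectionError(OnsightError):
    """Automatic ON/ONS contour selection found no admissible nested pair."""
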