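"""Exception hierarchy shared across the package.

``ValidationError`` marks bad user input (CLI exit code 1); ``ComputeError``
marks a failure during estimation itself (CLI exit code 2).
"""


class HibedError(Exception):
    """Base class for all package errors."""


class ValidationError(HibedError):
    """Input failed a structural or range check."""


class ComputeError(HibedError):
    """A computation could not be carried out on otherwise valid input."""


class CoverageError(ComputeError):
    """Too few reference-library probes are present in the bulk matrix."""
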