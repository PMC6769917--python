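"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: I/O problems -> 2, model/fit failures
-> 3, input validation -> 4.
"""


class FacProfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FacProfError):
    """Malformed or inconsistent input data (CLI exit code 4)."""


class InsufficientDataError(FacProfError):
    """Too few or degenerate points for a fit (CLI exit code 3)."""


class NoSaturableBindingError(FacProfError):
    """Woolf-Hofstee slope is non-negative: no saturable binding (exit 3)."""


class FrontDetectionError(FacProfError):
    """Elution front could not be located on a breakthrough curve (exit 3)."""


class ProfileEmptyError(FacProfError):
    """Every glycan in a profile is below detection (exit 3)."""
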