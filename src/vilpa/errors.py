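"""Exception hierarchy shared across the package.

Input problems (bad schema, bad configuration, bad arguments) and fitting
problems (non-convergence, degenerate designs) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class VilpaError(Exception):
    """Base class for all package errors."""


class InputError(VilpaError):
    """Invalid input data or arguments (exit code 1 at the CLI)."""


class ConfigurationError(InputError):
    """Invalid simulation or pipeline configuration; names the offending field."""


class FittingError(VilpaError):
    """Model fitting failed (exit code 2 at the CLI)."""


class NoBenefitError(VilpaError):
    """Raised when a dose-response curve never drops below HR 1, so no
    minimal dose (ED50) exists."""
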