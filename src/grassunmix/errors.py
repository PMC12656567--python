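"""Exception hierarchy with CLI exit-code mapping.

Exit codes: 0 success, 2 configuration error, 3 data error, 4 numerical failure.
"""


class GrassunmixError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(GrassunmixError):
    """Invalid or unparseable run configuration."""

    exit_code = 2


class DataError(GrassunmixError):
    """Malformed, inconsistent, or missing input data."""

    exit_code = 3


class NumericalError(GrassunmixError):
    """Numerical failure: rank deficiency, non-convergence, degenerate input."""

    exit_code = 4


class CollinearEndmembersError(NumericalError):
    """Endmember matrix is rank-deficient beyond tolerance."""

    def __init__(self, classes, message=None):
        self.classes = tuple(classes)
        super().__init__(
            message or f"near-collinear endmembers: {', '.join(self.classes)}"
        )
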