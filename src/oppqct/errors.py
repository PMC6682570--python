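"""Exception hierarchy used across the package."""


class OppQCTError(Exception):
    """Base class for all package errors."""


class InputError(OppQCTError):
    """Malformed or inconsistent input (mixed scanners, empty tables, ...)."""


class DegenerateDesignError(InputError):
    """A regression design without enough distinct support to fit."""


class NotAssessableError(OppQCTError):
    """No assessable measurement remains after exclusions."""


class GeometryError(OppQCTError):
    """A region of interest does not fit inside the volume."""


class ConfigError(OppQCTError):
    """Invalid simulation or analysis configuration."""


class NoEventsError(OppQCTError):
    """Survival data carry no events, so the hazard model is not estimable."""


class ConvergenceError(OppQCTError):
    """An iterative fit failed to converge; the message carries diagnostics."""
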