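"""Exception hierarchy shared across the package."""


class DsmCellError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DsmCellError, ValueError):
    """A parameter, geometry, or config document is invalid or unphysical."""


class IntegrationError(DsmCellError, RuntimeError):
    """The membrane integrator diverged or a linear solve failed."""


class BracketError(DsmCellError, ValueError):
    """A threshold search was given an invalid bracket (no spike at the
    upper endpoint, or a spike already at the lower endpoint)."""


class FitError(DsmCellError, RuntimeError):
    """A parameter fit failed to converge or was given degenerate data."""
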