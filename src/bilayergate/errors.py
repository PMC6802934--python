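"""Exception hierarchy.

All analysis errors derive from :class:`BilayerGateError` so callers can
catch the package's failures without masking programming errors.
"""


class BilayerGateError(Exception):
    """Base class for all bilayergate errors."""


class InvalidParameterError(BilayerGateError, ValueError):
    """A parameter violates its physical or numeric precondition."""


class GridMismatchError(BilayerGateError, ValueError):
    """Two curves do not share a common q grid (no silent interpolation)."""


class FitFailureError(BilayerGateError, RuntimeError):
    """A least-squares or EM fit failed to converge or is out of bounds.

    Carries diagnostics in ``.diagnostics`` (a dict) when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(FitFailureError):
    """The fit converged to a physically meaningless configuration."""


class SelectionError(BilayerGateError, KeyError):
    """An atom/residue/chain selection matched nothing that was required."""


class InsufficientDataError(BilayerGateError, ValueError):
    """Not enough points/events/frames for the requested estimate."""


class LevelDetectionError(BilayerGateError, RuntimeError):
    """The all-points histogram does not resolve two current levels."""


class ParseError(BilayerGateError, ValueError):
    """A structured input file could not be parsed."""
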