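"""Exception hierarchy shared across the package."""


class AdipoSwitchError(Exception):
    """Base class for package errors."""


class InputDomainError(AdipoSwitchError, ValueError):
    """An argument lies outside the domain an operation is defined on."""


class NumericalError(AdipoSwitchError, RuntimeError):
    """An iterative numerical procedure failed to converge.

    Carries an optional ``diagnostics`` dict with the offending state.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FlatCurveError(AdipoSwitchError, ValueError):
    """Dose-response data has too little dynamic range to fit a sigmoid."""


class PlacementError(AdipoSwitchError, RuntimeError):
    """Synthetic cells could not be placed at the requested density."""
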