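"""Exception hierarchy shared across the package."""


class NetOverlapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetOverlapError, ValueError):
    """An input file does not match any supported dialect."""


class ParameterError(NetOverlapError, ValueError):
    """A parameter is outside its valid domain."""


class EmptyInteractomeError(NetOverlapError, ValueError):
    """No seed gene of a +1 interactome is present in the network."""


class SimulationError(NetOverlapError, RuntimeError):
    """A Monte Carlo construction could not be completed."""

    def __init__(self, message: str, achieved_size: int | None = None):
        super().__init__(message)
        self.achieved_size = achieved_size


class FitError(NetOverlapError, RuntimeError):
    """A regression fit has too few usable points."""
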