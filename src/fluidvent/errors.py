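"""Exception hierarchy for fluidvent."""


class FluidventError(Exception):
    """Base class for all fluidvent errors."""


class ConfigurationError(FluidventError):
    """A parameter block violates its invariants (e.g. P_high <= P_low)."""


class NonOscillationError(FluidventError):
    """The coupled diverter-lung system failed to sustain oscillation.

    Raised by the engine when no phase switch occurs within ten expected
    periods, or when a run completes without a single complete cycle.  The
    message names the violated condition (e.g. zero source flow).
    """


class InsufficientDataError(FluidventError):
    """A waveform or cycle list is too short for the requested analysis."""
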