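"""Exception hierarchy shared across the toolkit."""


class MrprError(Exception):
    """Base class for all toolkit errors."""


class InputError(MrprError, ValueError):
    """Invalid user input (bad coordinates, non-physical parameters, ...)."""


class NoCandidatePeakError(MrprError):
    """No coverage peak exceeded the detection threshold.

    Raised by adaptive peak-width estimation; supply ``fixed_width`` to
    bypass the estimate on featureless tracks.
    """


class DegenerateBackgroundError(MrprError):
    """Called peaks absorb the entire track coverage, leaving no background."""


class FitError(MrprError):
    """A least-squares model fit failed to converge or is degenerate."""
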