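"""Exception hierarchy for voltspike.

Per-neuron processing raises these; the orchestrator records them per slot
instead of aborting sibling neurons.
"""


class VoltSpikeError(Exception):
    """Base class for all voltspike errors."""


class MovieFormatError(VoltSpikeError):
    """Input file is not a T x H x W movie."""


class TooFewPeaksError(VoltSpikeError):
    """Not enough local maxima to estimate a peak-height distribution."""


class DegenerateTraceError(VoltSpikeError):
    """Trace has no negative samples; the noise level is undefined."""


class NoTemplateError(VoltSpikeError):
    """No spike survives edge trimming; a template cannot be formed."""


class NoNoiseSamplesError(VoltSpikeError):
    """Spike train covers the whole trace; no noise samples remain."""


class EmptyBackgroundError(VoltSpikeError):
    """Context region leaves no background pixels; enlarge the margin."""
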