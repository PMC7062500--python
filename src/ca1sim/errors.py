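"""Exception hierarchy for ca1sim."""


class CA1SimError(Exception):
    """Base class for all ca1sim errors."""


class SWCFormatError(CA1SimError):
    """Malformed SWC content (bad columns, orphan parents, bad radii)."""


class MorphologyStructureError(CA1SimError):
    """Structurally invalid tree (cycles, disconnected points)."""


class ClassificationError(CA1SimError):
    """Region classification cannot proceed (e.g. no apical sections)."""


class DiscretizationError(CA1SimError):
    """Invalid geometry or parameters during spatial discretization."""


class NumericalError(CA1SimError):
    """Linear-algebra failure (singular diagonal) in the cable solver."""


class DivergenceError(NumericalError):
    """Non-finite state during time integration."""

    def __init__(self, message, compartment=None, time=None):
        super().__init__(message)
        self.compartment = compartment
        self.time = time


class ConfigurationError(CA1SimError):
    """Unknown mechanism / invalid manipulation or experiment config."""


class ProtocolError(CA1SimError):
    """A stimulation protocol precondition failed (e.g. 0 or >1 somatic APs)."""


class PlacementError(ProtocolError):
    """Not enough eligible cable to place the requested synapses."""


class MetricError(CA1SimError):
    """A waveform metric is undefined on the given trace."""
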