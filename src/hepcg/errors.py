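"""Exception hierarchy for hepcg."""


class HepcgError(Exception):
    """Base class for all hepcg errors."""


class InvalidChainError(HepcgError):
    """Chain specification violates a topology precondition (e.g. dp < 2)."""


class TopologyMismatchError(HepcgError):
    """Template/anchor counts are inconsistent with the requested chain."""


class InvalidGeometryError(HepcgError):
    """Internal coordinates outside their valid ranges."""


class ParameterError(HepcgError):
    """A force-field or electrolyte parameter violates its invariant."""


class ConfigurationError(HepcgError):
    """Run configuration is incomplete or inconsistent."""


class SingularityError(HepcgError):
    """Energy/force evaluation requested at a singular geometry (r = 0)."""


class SimulationBlowupError(HepcgError):
    """Non-finite coordinates or forces during dynamics.

    Carries the last finite frame for diagnosis.
    """

    def __init__(self, message, last_good_frame=None, step=None):
        super().__init__(message)
        self.last_good_frame = last_good_frame
        self.step = step


class AlignmentError(HepcgError):
    """Structure superposition with mismatched point counts."""


class FormatError(HepcgError):
    """Unreadable or malformed input file."""
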