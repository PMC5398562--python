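"""Exception hierarchy.

All domain errors derive from :class:`ReplicytoError` so callers (and the CLI)
can distinguish user/parameter problems from genuine bugs.
"""


class ReplicytoError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ReplicytoError, ValueError):
    """A parameter violates its documented domain (fractions, sizes, ranges)."""


class PresetLookupError(ReplicytoError, KeyError):
    """Unknown preset name; the message lists the available presets."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


class PlacementError(ReplicytoError, ValueError):
    """A nucleus does not fit inside the image bounds at its radius."""


class ProfileError(ReplicytoError, RuntimeError):
    """Cell-cycle profiling failed (e.g. fewer than two DNA modes).

    Carries the diagnostic DNA histogram (``bin_centers``, ``counts``) that was
    searched for modes, to help the caller see why gating failed.
    """

    def __init__(self, message: str, bin_centers=None, counts=None):
        super().__init__(message)
        self.bin_centers = bin_centers
        self.counts = counts
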