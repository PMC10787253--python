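"""Exception hierarchy for histotile.

All histotile errors derive from :class:`HistotileError` so callers can
catch the package's failures with a single except clause while still
distinguishing the standard-library categories (ValueError, KeyError, ...)
each concrete error also inherits.
"""


class HistotileError(Exception):
    """Base class for all histotile errors."""


class SlideFormatError(HistotileError, ValueError):
    """The file is not a readable pyramidal slide."""


class MetadataError(HistotileError, ValueError):
    """Required slide metadata (MPP, objective power) is absent."""


class MagnificationError(HistotileError, ValueError):
    """No pyramid level matches the requested magnification exactly."""


class ROIValidationError(HistotileError, ValueError):
    """A polygon ROI violates its invariants (too few vertices,
    zero area, or self-intersection)."""


class ConfigurationError(HistotileError, ValueError):
    """An unknown detector, augmentation op, or option name."""


class IntegrityError(HistotileError, ValueError):
    """A dataset on disk is internally inconsistent."""


class ManifestParseError(HistotileError, ValueError):
    """A descriptions CSV could not be parsed."""


class EarlyStopStateError(HistotileError, RuntimeError):
    """early_stop_update called on an already-stopped state."""
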