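"""Exception hierarchy for the HD-EMG pipeline."""


class HdemgError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HdemgError):
    """A bundle or manifest on disk is malformed or incomplete."""


class IntegrityError(HdemgError):
    """Metadata and data disagree (e.g. channel-count mismatch)."""


class ParameterError(HdemgError, ValueError):
    """An argument is outside its valid domain."""


class InsufficientDataError(HdemgError):
    """The recording is too short for the requested operation."""


class InsufficientEpochsError(HdemgError):
    """Fewer qualifying epochs than requested."""

    def __init__(self, requested: int, available: int, message: str | None = None):
        self.requested = requested
        self.available = available
        super().__init__(
            message
            or f"requested {requested} epochs but only {available} qualify "
            f"(shortfall {requested - available})"
        )


class AdaptationError(HdemgError):
    """The adaptive interference canceller diverged."""


class InterpolationError(HdemgError):
    """Bad-channel interpolation is impossible (e.g. no good cells)."""


class UndefinedFeatureError(HdemgError):
    """A feature is undefined for this input (e.g. CG of an all-zero map)."""


class BalanceError(HdemgError):
    """Class counts are unequal where a balanced design is required."""


class CompletenessError(HdemgError):
    """A session is missing recordings a protocol requires."""


class SegmentationError(HdemgError):
    """An endurance recording is too short to segment."""


class DegenerateTestError(HdemgError):
    """A statistical test is undefined for this input (zero variance)."""
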