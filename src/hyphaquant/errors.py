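"""Exception types shared across the pipeline."""


class HyphaQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(HyphaQuantError):
    """A hyphal model or measurement geometry is degenerate (e.g. zero length)."""


class OutOfFieldError(HyphaQuantError):
    """One or more puncta fall outside the rendered field of view."""

    def __init__(self, punctum_ids):
        self.punctum_ids = sorted(set(punctum_ids))
        super().__init__(f"puncta outside field of view: {self.punctum_ids}")


class MovieFormatError(HyphaQuantError):
    """An on-disk movie is malformed or missing required calibration metadata."""


class BlindingError(HyphaQuantError):
    """Blinded-name generation collided or the input file list is invalid."""


class DegenerateHistogramError(HyphaQuantError):
    """An automatic threshold was requested for a single-valued image."""


class UndefinedStatisticError(HyphaQuantError):
    """A statistic is undefined for the given inputs (empty mask, zero variance...)."""


class AlignmentError(HyphaQuantError):
    """A movement-aligned profile could not be registered (flat reference)."""


class MissingSeptumError(HyphaQuantError):
    """A septum crop contains no septum marker signal."""


class ConfigError(HyphaQuantError):
    """A quantification config failed validation."""
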