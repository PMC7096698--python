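"""Exception hierarchy for psmdkit."""


class PsmdKitError(Exception):
    """Base class for all psmdkit errors."""


class ShapeMismatchError(PsmdKitError):
    """Volumes that must share a grid do not."""


class EmptySkeletonError(PsmdKitError):
    """No skeleton voxels survive masking."""


class EmptyMaskError(PsmdKitError):
    """A brain or region mask contains no foreground voxels."""


class PlacementError(PsmdKitError):
    """A requested lesion blob does not fit inside the brain mask."""


class RatingValidationError(PsmdKitError):
    """An SVD rating field is outside its allowed range."""


class CollinearityError(PsmdKitError):
    """The predictor matrix is rank deficient."""


class DegenerateDataError(PsmdKitError):
    """Input data admit no meaningful estimate (zero spread, single class...)."""
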