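"""Exception hierarchy for the hsifruit pipeline."""


class HsiFruitError(Exception):
    """Base class for all hsifruit errors."""


class DegenerateReferenceError(HsiFruitError):
    """White minus dark reference is (near) zero at some element."""


class FormatError(HsiFruitError):
    """A container on disk is inconsistent (axis/band mismatch, bad header)."""


class CapacityError(HsiFruitError):
    """The requested number of fruits does not fit in the scene."""


class WavelengthRangeError(HsiFruitError, ValueError):
    """A requested wavelength or band index is outside the axis."""


class DegenerateImageError(HsiFruitError):
    """Automatic thresholding received a constant image."""


class EmptySceneError(HsiFruitError):
    """No connected component survived the minimum-area filter."""


class ShapeMismatchError(HsiFruitError):
    """Two arrays that must share spatial layout do not."""


class SpectrumLengthError(HsiFruitError):
    """Spectrum too short (or of unusable length) for the wavelet transform."""


class NormalizationError(HsiFruitError):
    """Area normalization of a zero-sum spectrum."""


class EmptyInputError(HsiFruitError):
    """An operation requiring at least one sample/pixel received none."""


class ParameterError(HsiFruitError, ValueError):
    """Invalid derivative/selection parameter combination."""


class RankError(HsiFruitError):
    """More latent variables requested than the data rank supports."""


class StratificationError(HsiFruitError):
    """Cross-validation folds cannot be stratified (class too small)."""


class ArchitectureError(HsiFruitError):
    """Network input too short to survive the conv/pool stack."""


class SplitCountError(HsiFruitError):
    """Per-split class counts do not sum to the class totals."""


class ReportError(HsiFruitError):
    """A report was requested with predictions missing for some split."""
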