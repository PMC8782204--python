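"""Named exceptions raised across the pipeline."""


class SeegQuakeError(Exception):
    """Base class for all package-specific errors."""


class NonVolumeError(SeegQuakeError, ValueError):
    """Image on disk is not a 3D scalar volume."""


class SingularAffineError(SeegQuakeError, ValueError):
    """Voxel-to-mm affine is not invertible."""


class DuplicateChannelError(SeegQuakeError, ValueError):
    """Recording contains repeated channel names."""


class SamplingRateError(SeegQuakeError, ValueError):
    """Sampling rate is missing, non-positive, or too low for a filter band."""


class EmptyCloudError(SeegQuakeError, ValueError):
    """No voxel survived the extraction threshold; adjust the thresholding rule."""


class DegenerateClusterError(SeegQuakeError, RuntimeError):
    """A mixture component collapsed below the minimum member count."""


class PlacementError(SeegQuakeError, RuntimeError):
    """Synthetic electrodes could not be placed with the required separation."""


class NoMassError(SeegQuakeError, RuntimeError):
    """Center-of-mass box contains no intensity mass."""


class NoContactsError(SeegQuakeError, RuntimeError):
    """Contact segmentation produced zero contacts for an electrode."""


class ZeroBaselineError(SeegQuakeError, ValueError):
    """A channel has zero energy over the baseline segment; cannot normalize."""


class SingleClassError(SeegQuakeError, ValueError):
    """ROC evaluation needs at least one positive and one negative label."""
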