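"""Plant mask from the chlorophyll fluorescence channel.

Under blue excitation and a long-pass filter, only chlorophyll-containing
tissue appears bright, so thresholding the fluorescence image yields a mask
of photosynthetically active pixels — the plant area over which spectral
indices and the projected canopy size are computed.

Conventions fixed across the package: foreground is *strictly above* the
threshold; connected components use 8-connectivity; the mask is computed
after registration so its frame matches all index channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, ParameterError
from .stack import FLUORESCENCE_CHANNEL, SpectralStack


@dataclass
class SegmentationParams:
    """Controls for mask construction.

    method
        ``otsu`` (parameter-free histogram threshold, the default) or
        ``fixed`` (use ``fixed_threshold``).
    fixed_threshold
        Intensity in [0, 1]; required iff ``method == "fixed"``.
    open_radius, close_radius
        Disk radii (pixels) for morphological opening then closing; 0
        disables the step.
    min_component_px
        Connected components smaller than this are removed.  The default
        (50 px) drops specks of noise while keeping trailing shoots that
        appear as separate blobs.
    keep
        ``all_components`` (default; a trailing plant may legitimately be
        several blobs) or ``largest_only``.
    """

    method: str = "otsu"
    fixed_threshold: float | None = None
    open_radius: int = 0
    close_radius: int = 0
    min_component_px: int = 50
    keep: str = "all_components"

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ParameterError(f"unknown segmentation method {self.method!r}")
        if self.method == "fixed":
            if self.fixed_threshold is None:
                raise ParameterError("method='fixed' requires fixed_threshold")
            if not (0.0 <= self.fixed_threshold <= 1.0):
                raise ParameterError("fixed_threshold must lie in [0, 1]")
        elif self.fixed_threshold is not None:
            raise ParameterError("fixed_threshold is only valid with method='fixed'")
        for name in ("open_radius", "close_radius", "min_component_px"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ParameterError(f"{name} must be a non-negative integer")
        if self.keep not in ("all_components", "largest_only"):
            raise ParameterError(f"unknown keep policy {self.keep!r}")


class PlantMask:
    """Boolean raster of plant pixels plus provenance.

    ``n_components`` is the 8-connected component count; an empty mask is
    permitted (``is_empty``) but must be handled explicitly downstream.
    """

    def __init__(
        self,
        mask: np.ndarray,
        threshold_used: float,
        n_components: int | None = None,
        source: str = FLUORESCENCE_CHANNEL,
    ) -> None:
        self.mask = np.asarray(mask, dtype=bool)
        self.threshold_used = float(threshold_used)
        if n_components is None:
            n_components = count_components(self.mask)
        self.n_components = int(n_components)
        self.source = source

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PlantMask(shape={self.shape}, pixels={int(self.mask.sum())}, "
            f"threshold={self.threshold_used:.4f}, components={self.n_components})"
        )


def count_components(mask: np.ndarray) -> int:
    """8-connected component count of a boolean raster."""
    if not mask.any():
        return 0
    _labels, n = measure.label(mask, connectivity=2, return_num=True)
    return int(n)


def compute_mask(stack: SpectralStack, params: SegmentationParams | None = None) -> PlantMask:
    """Threshold the fluorescence channel and clean up the result.

    Pipeline: threshold (strictly above) -> morphological opening ->
    closing -> removal of small components -> optional largest-component
    selection.  The threshold actually used is recorded so any fixed value
    can reproduce a given mask later.

    Raises
    ------
    MissingChannelError
        The stack has no ``chlf`` channel.
    DegenerateHistogramError
        Otsu thresholding on a constant image.
    """
    if params is None:
        params = SegmentationParams()
    chlf = stack.channel(FLUORESCENCE_CHANNEL)

    if params.method == "otsu":
        if float(chlf.min()) == float(chlf.max()):
            raise DegenerateHistogramError(
                "fluorescence image is constant; Otsu threshold undefined"
            )
        threshold = float(threshold_otsu(chlf))
    else:
        threshold = float(params.fixed_threshold)

    mask = chlf > threshold
    if params.open_radius > 0:
        mask = morphology.binary_opening(mask, morphology.disk(params.open_radius))
    if params.close_radius > 0:
        mask = morphology.binary_closing(mask, morphology.disk(params.close_radius))
    if params.min_component_px > 1 and mask.any():
        # components strictly smaller than min_component_px are removed
        mask = morphology.remove_small_objects(
            mask, max_size=params.min_component_px - 1, connectivity=2
        )
    if params.keep == "largest_only" and mask.any():
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return PlantMask(mask=mask, threshold_used=threshold, source=FLUORESCENCE_CHANNEL)


def mask_pixel_count(mask: PlantMask | np.ndarray) -> int:
    """Projected canopy size: the number of plant pixels in the mask.

    A simple sum over the boolean raster; the 2D proxy for plant biomass.
    """
    arr = mask.mask if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    return int(arr.sum())
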