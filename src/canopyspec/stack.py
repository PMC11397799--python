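"""Core raster containers: channel labels and the spectral stack.

A spectral stack is the set of co-registered single-wavelength images of one
plant at one timepoint, captured sequentially under different LED
illuminations.  The five semantic channels are fixed: red, green, blue,
near-infrared (``nir``) and chlorophyll fluorescence (``chlf``).

Conventions used throughout the package:

* rasters are 2D float arrays of normalized intensity in [0, 1];
* addressing is ``(row, col)``, 0-based, row 0 at the image top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingChannelError, StackError

#: Closed set of semantic channel labels.
CHANNEL_LABELS: tuple[str, ...] = ("red", "green", "blue", "nir", "chlf")

#: The channel used to build the plant mask.
FLUORESCENCE_CHANNEL = "chlf"


def validate_channel_label(name: str) -> str:
    """Return ``name`` if it is one of the allowed channel labels.

    Raises
    ------
    ValueError
        If the label is not in :data:`CHANNEL_LABELS`; the message lists
        the allowed labels.
    """
    if name not in CHANNEL_LABELS:
        raise ValueError(
            f"unknown channel label {name!r}; allowed labels are "
            f"{', '.join(CHANNEL_LABELS)}"
        )
    return name


@dataclass
class SpectralStack:
    """Co-registered set of single-wavelength rasters for one plant/timepoint.

    Parameters
    ----------
    channels
        Mapping from channel label to a 2D float array with values in
        [0, 1].  All rasters must share one shape.
    plant_id, timepoint
        Identifiers from the manifest.
    treatment
        Optional numeric treatment level (e.g. fertilizer g/pot, or pH).
    bit_depth_in
        Bit depth of the source files (8 or 16); informational.
    invalid
        Optional boolean raster marking pixels that are not trustworthy for
        index computation (e.g. moved out of frame by registration).  True
        means invalid.
    """

    channels: dict[str, np.ndarray]
    plant_id: str = ""
    timepoint: str = ""
    treatment: float | None = None
    bit_depth_in: int = 8
    invalid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.channels:
            raise StackError("a spectral stack needs at least one channel")
        shapes = set()
        for name, arr in self.channels.items():
            validate_channel_label(name)
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise StackError(f"channel {name!r} is not a 2D raster")
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise StackError(
                    f"channel {name!r} has intensities outside [0, 1]"
                )
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise StackError(
                f"channels disagree on dimensions: {sorted(shapes)}"
            )
        if self.invalid is not None:
            self.invalid = np.asarray(self.invalid, dtype=bool)
            if self.invalid.shape != self.shape:
                raise StackError("invalid-pixel raster shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel raster, or raise :class:`MissingChannelError`."""
        validate_channel_label(name)
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"stack for plant {self.plant_id!r} at {self.timepoint!r} "
                f"has no {name!r} channel (present: {sorted(self.channels)})"
            ) from None

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    def invalid_mask(self) -> np.ndarray:
        """Boolean raster of untrustworthy pixels (False everywhere if unset)."""
        if self.invalid is None:
            return np.zeros(self.shape, dtype=bool)
        return self.invalid

    def copy(self) -> "SpectralStack":
        return SpectralStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            plant_id=self.plant_id,
            timepoint=self.timepoint,
            treatment=self.treatment,
            bit_depth_in=self.bit_depth_in,
            invalid=None if self.invalid is None else self.invalid.copy(),
        )
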