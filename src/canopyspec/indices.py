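"""Per-pixel spectral index maps over the plant mask.

NDVI follows the universal definition, per pixel::

    NDVI = (NIR - red) / (NIR + red)

bounded in [-1, 1]; dense healthy vegetation reflects strongly in NIR and
absorbs red, pushing NDVI toward 1.

ACI (anthocyanin content index) tracks red pigmentation.  The system lacks
the red-edge bands of standard anthocyanin indices, so the default here is
the per-pixel red/green ratio; alternative two-band ratios can be selected
through the formula registry, and every map records its ``formula_id`` so
outputs are self-describing.

Indices are computed on normalized digital numbers, not calibrated
reflectance (no calibration target in the acquisition protocol) — a
documented limitation, acceptable because treatments are compared within
one system.

Invalid pixels — off the mask, zero denominator, or flagged out-of-frame by
registration — carry NaN in ``values`` but are authoritative in the
``valid`` raster and are excluded from every statistic, histogram and
rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import PlantMask
from .stack import SpectralStack

#: Two-band ratio formulas available for ACI; keys are formula ids.
ACI_FORMULAS: dict[str, tuple[str, str]] = {
    "red/green": ("red", "green"),
    "green/nir": ("green", "nir"),
    "red/nir": ("red", "nir"),
}

DEFAULT_ACI_FORMULA = "red/green"


@dataclass
class IndexMap:
    """One spectral index evaluated per pixel within the plant mask."""

    name: str
    values: np.ndarray
    valid: np.ndarray
    formula_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid rasters must share a shape")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        """1D array of the index at valid pixels only."""
        return self.values[self.valid]


@dataclass
class IndexStats:
    """Mean/SD over valid pixels; ``defined`` is False for an empty set."""

    mean: float | None
    sd: float | None
    n_valid: int

    @property
    def defined(self) -> bool:
        return self.n_valid > 0


def _masked_ratio_map(
    name: str,
    numerator: np.ndarray,
    denominator: np.ndarray,
    mask: PlantMask,
    stack_invalid: np.ndarray,
    formula_id: str,
) -> IndexMap:
    valid = mask.mask & ~stack_invalid & (denominator != 0.0)
    values = np.full(numerator.shape, np.nan)
    np.divide(numerator, denominator, out=values, where=valid)
    return IndexMap(name=name, values=values, valid=valid, formula_id=formula_id)


def compute_ndvi(stack: SpectralStack, mask: PlantMask) -> IndexMap:
    """NDVI = (nir - red)/(nir + red) at each masked pixel.

    Pixels where nir + red = 0, pixels off the mask, and pixels flagged
    invalid by registration are all excluded.  Expects registration to
    have been applied already when the source hardware misaligns NIR.

    Raises :class:`MissingChannelError` if nir or red is absent.
    """
    nir = stack.channel("nir")
    red = stack.channel("red")
    return _masked_ratio_map(
        "NDVI", nir - red, nir + red, mask, stack.invalid_mask(), "(nir-red)/(nir+red)"
    )


def compute_aci(
    stack: SpectralStack, mask: PlantMask, formula: str = DEFAULT_ACI_FORMULA
) -> IndexMap:
    """Anthocyanin content index: a two-band ratio, red/green by default.

    Pixels with a zero denominator are invalid and excluded from all
    statistics.  The formula id is recorded on the map.
    """
    try:
        num_name, den_name = ACI_FORMULAS[formula]
    except KeyError:
        raise ValueError(
            f"unknown ACI formula {formula!r}; available: {sorted(ACI_FORMULAS)}"
        ) from None
    num = stack.channel(num_name)
    den = stack.channel(den_name)
    return _masked_ratio_map("ACI", num, den, mask, stack.invalid_mask(), formula)


def index_statistics(index_map: IndexMap) -> IndexStats:
    """Mean and population SD of an index over its valid pixels.

    An empty valid set yields an undefined-flagged result (mean and sd are
    None, ``defined`` is False) rather than silently propagating NaN.
    """
    vals = index_map.valid_values()
    n = vals.size
    if n == 0:
        return IndexStats(mean=None, sd=None, n_valid=0)
    return IndexStats(mean=float(vals.mean()), sd=float(vals.std(ddof=0)), n_valid=n)
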