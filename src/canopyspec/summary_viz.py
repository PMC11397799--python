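"""Per-plant canopy summaries and graphical outputs.

Assembles the scalar metrics extracted from one stack (projected canopy
size, index means/SDs, fluorescence mean) and renders the two graphical
products of the pipeline: false-color index images and index histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import numpy as np

from .errors import ParameterError
from .indices import IndexMap, index_statistics
from .segmentation import PlantMask, mask_pixel_count
from .stack import FLUORESCENCE_CHANNEL, SpectralStack

#: Fixed default display ranges per index for stable visual comparison
#: across timepoints.
DEFAULT_DISPLAY_RANGE: dict[str, tuple[float, float]] = {
    "NDVI": (-0.2, 0.9),
    "ACI": (0.0, 2.0),
}

#: Colormap used for false-color rendering; recorded in output metadata.
DEFAULT_COLORMAP = "viridis"

DEFAULT_HISTOGRAM_BINS = 50

#: Theoretical index ranges used as default histogram support.
INDEX_RANGE: dict[str, tuple[float, float]] = {
    "NDVI": (-1.0, 1.0),
    "ACI": (0.0, 5.0),
}


@dataclass
class CanopySummary:
    """Scalar per-plant metrics for one timepoint.

    Means/SDs are None (undefined) when the corresponding valid pixel set
    is empty; ``chlf_mean`` averages the fluorescence channel over the
    plant mask itself, since fluorescence defines the mask.
    """

    plant_id: str
    timepoint: str
    treatment: float | None
    canopy_size_px: int
    ndvi_mean: float | None = None
    ndvi_sd: float | None = None
    aci_mean: float | None = None
    aci_sd: float | None = None
    chlf_mean: float | None = None


@dataclass
class Histogram:
    """Counts of valid index pixels over strictly increasing bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("edges and counts must be 1D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need B+1 edges for B counts")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def summarize_plant(
    stack: SpectralStack, mask: PlantMask, maps: list[IndexMap]
) -> CanopySummary:
    """Collapse one stack + mask + index maps into scalar metrics.

    Index means/SDs come from :func:`index_statistics` (single source of
    truth); an empty mask yields canopy_size_px = 0 and undefined means.
    """
    summary = CanopySummary(
        plant_id=stack.plant_id,
        timepoint=stack.timepoint,
        treatment=stack.treatment,
        canopy_size_px=mask_pixel_count(mask),
    )
    for index_map in maps:
        stats = index_statistics(index_map)
        if index_map.name == "NDVI":
            summary.ndvi_mean, summary.ndvi_sd = stats.mean, stats.sd
        elif index_map.name == "ACI":
            summary.aci_mean, summary.aci_sd = stats.mean, stats.sd
    if stack.has_channel(FLUORESCENCE_CHANNEL) and not mask.is_empty:
        chlf = stack.channel(FLUORESCENCE_CHANNEL)
        summary.chlf_mean = float(chlf[mask.mask].mean())
    return summary


def render_false_color(
    index_map: IndexMap,
    vmin: float | None = None,
    vmax: float | None = None,
    colormap: str = DEFAULT_COLORMAP,
) -> np.ndarray:
    """Map an index raster through a fixed colormap to an RGB uint8 image.

    Values are clipped into [vmin, vmax]; invalid pixels render black.
    The output is a pure function of (map, vmin, vmax, colormap id), so
    repeated renders are byte-identical.
    """
    if vmin is None or vmax is None:
        lo, hi = DEFAULT_DISPLAY_RANGE.get(index_map.name, (0.0, 1.0))
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax
    if not vmin < vmax:
        raise ParameterError(f"vmin ({vmin}) must be < vmax ({vmax})")
    cmap = matplotlib.colormaps[colormap]
    scaled = np.zeros(index_map.values.shape)
    valid = index_map.valid
    scaled[valid] = np.clip(
        (index_map.values[valid] - vmin) / (vmax - vmin), 0.0, 1.0
    )
    rgba = cmap(scaled)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~valid] = 0
    return rgb


def save_false_color_png(
    index_map: IndexMap,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
    colormap: str = DEFAULT_COLORMAP,
) -> None:
    """Write the false-color rendering plus an adjacent color scale bar.

    A ``<name>.scale.png`` with the colormap gradient and the value range
    in the filename metadata is emitted alongside the image.
    """
    import imageio.v3 as iio

    rgb = render_false_color(index_map, vmin=vmin, vmax=vmax, colormap=colormap)
    path = Path(path)
    iio.imwrite(path, rgb)
    if vmin is None or vmax is None:
        vmin, vmax = DEFAULT_DISPLAY_RANGE.get(index_map.name, (0.0, 1.0))
    cmap = matplotlib.colormaps[colormap]
    gradient = np.tile(np.linspace(0.0, 1.0, 256), (16, 1))
    bar = (cmap(gradient)[..., :3] * 255).round().astype(np.uint8)
    iio.imwrite(path.with_suffix(f".scale_{vmin:g}_{vmax:g}.png"), bar)


def compute_histogram(
    index_map: IndexMap,
    bins: int = DEFAULT_HISTOGRAM_BINS,
    value_range: tuple[float, float] | None = None,
) -> Histogram:
    """Histogram of valid index pixels.

    Out-of-range values are clipped into the end bins so that counts
    always sum to ``n_valid`` (conservation).  The default range is the
    index's theoretical support.
    """
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    if value_range is None:
        value_range = INDEX_RANGE.get(index_map.name, (0.0, 1.0))
    lo, hi = value_range
    if not lo < hi:
        raise ParameterError("histogram range must be increasing")
    vals = np.clip(index_map.valid_values(), lo, hi)
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts, index_name=index_map.name)


def save_histogram(hist: Histogram, csv_path: str | Path, png_path: str | Path | None = None) -> None:
    """Write a histogram as CSV (bin_left, bin_right, count) and optional PNG."""
    import csv as _csv

    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "count"])
        for i, c in enumerate(hist.counts):
            writer.writerow(
                [f"{hist.bin_edges[i]:.9g}", f"{hist.bin_edges[i + 1]:.9g}", int(c)]
            )
    if png_path is not None:
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        widths = np.diff(hist.bin_edges)
        ax.bar(hist.bin_edges[:-1], hist.counts, width=widths, align="edge")
        ax.set_xlabel(hist.index_name)
        ax.set_ylabel("pixel count")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
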