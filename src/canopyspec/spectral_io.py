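"""Manifest-driven image I/O.

Input images are single-channel PNG or TIFF files, 8- or 16-bit, one file
per LED wavelength.  Which file belongs to which (plant, timepoint, channel)
is declared in an explicit CSV manifest rather than inferred from file
names.  Intensities are normalized to [0, 1] floats at load time by
dividing by ``2**bit_depth - 1``; all downstream math operates on the
normalized values, which makes band ratios bit-depth invariant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ChannelError, ManifestFormatError, ManifestValidationError, StackError
from .stack import CHANNEL_LABELS, SpectralStack

MANIFEST_COLUMNS = ("plant_id", "timepoint", "treatment", "channel", "file")


@dataclass(frozen=True)
class ManifestRecord:
    plant_id: str
    timepoint: str
    treatment: float | None
    channel: str
    path: Path


@dataclass
class Manifest:
    """Validated list of image records plus the directory they live under."""

    records: list[ManifestRecord]
    root: Path

    def stacks(self) -> list[tuple[str, str]]:
        """Distinct (plant_id, timepoint) pairs, in first-seen order."""
        seen: dict[tuple[str, str], None] = {}
        for rec in self.records:
            seen.setdefault((rec.plant_id, rec.timepoint), None)
        return list(seen)

    def select(self, plant_id: str, timepoint: str) -> list[ManifestRecord]:
        return [
            r
            for r in self.records
            if r.plant_id == plant_id and r.timepoint == timepoint
        ]


def parse_manifest(path: str | Path) -> Manifest:
    """Read and validate a CSV manifest.

    The CSV must carry a header with columns
    ``plant_id,timepoint,treatment,channel,file``.  Every record is either
    accepted or rejected with a named error — no silent drops.

    Raises
    ------
    ManifestFormatError
        Missing file or missing required header columns.
    ManifestValidationError
        Unknown channel label, duplicate (plant, timepoint, channel)
        triple, or unreadable row.
    """
    path = Path(path)
    if not path.is_file():
        raise ManifestFormatError(f"manifest not found: {path}")
    root = path.parent

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ManifestFormatError(
                f"manifest {path} is missing required columns: {missing}"
            )
        records: list[ManifestRecord] = []
        seen: set[tuple[str, str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            channel = (row["channel"] or "").strip()
            if channel not in CHANNEL_LABELS:
                raise ManifestValidationError(
                    f"line {lineno}: unknown channel {channel!r}; allowed "
                    f"labels are {', '.join(CHANNEL_LABELS)}"
                )
            plant_id = (row["plant_id"] or "").strip()
            timepoint = (row["timepoint"] or "").strip()
            triple = (plant_id, timepoint, channel)
            if triple in seen:
                raise ManifestValidationError(
                    f"line {lineno}: duplicate (plant_id, timepoint, channel) "
                    f"triple {triple}"
                )
            seen.add(triple)
            raw_treat = (row["treatment"] or "").strip()
            treatment = float(raw_treat) if raw_treat else None
            file_field = (row["file"] or "").strip()
            if not file_field:
                raise ManifestValidationError(f"line {lineno}: empty file path")
            records.append(
                ManifestRecord(plant_id, timepoint, treatment, channel, root / file_field)
            )
    return Manifest(records=records, root=root)


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ChannelError(
        f"unsupported pixel dtype {arr.dtype}; expected 8- or 16-bit unsigned"
    )


def read_channel_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a single-channel 8/16-bit image, returning (normalized array, bit depth).

    Raises :class:`ChannelError` for RGB(A) files or unsupported dtypes.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        raise ChannelError(
            f"{path}: multi-channel (shape {arr.shape}) where single-channel "
            "grayscale was expected"
        )
    if arr.ndim != 2:
        raise ChannelError(f"{path}: unexpected image dimensionality {arr.ndim}")
    depth = _bit_depth_of(arr)
    return arr.astype(float) / float(2**depth - 1), depth


def load_stack(manifest: Manifest, plant_id: str, timepoint: str) -> SpectralStack:
    """Load all channels for one (plant, timepoint) into a spectral stack.

    All channel images must decode to grayscale rasters of identical
    dimensions; intensities are normalized into [0, 1].

    Raises
    ------
    ManifestValidationError
        No records exist for the requested pair.
    StackError
        Channel dimensions disagree, or mixed bit depths within one stack.
    ChannelError
        A file is not single-channel 8/16-bit grayscale.
    """
    records = manifest.select(plant_id, timepoint)
    if not records:
        raise ManifestValidationError(
            f"manifest has no records for plant {plant_id!r} at {timepoint!r}"
        )
    channels: dict[str, np.ndarray] = {}
    depths: set[int] = set()
    treatment = None
    # Multi-page TIFF dialect: several records sharing one .tif file take
    # their channels from its pages, in manifest record order.
    shared: dict[Path, list[ManifestRecord]] = {}
    for rec in records:
        shared.setdefault(rec.path, []).append(rec)
    for path, recs in shared.items():
        if len(recs) > 1:
            if path.suffix.lower() not in (".tif", ".tiff"):
                raise ManifestValidationError(
                    f"{path}: multiple channels may share a file only for "
                    "multi-page TIFF"
                )
            import tifffile

            pages = tifffile.imread(path)
            if pages.ndim == 2:
                pages = pages[None]
            if pages.ndim != 3:
                raise ChannelError(f"{path}: unexpected TIFF shape {pages.shape}")
            if len(pages) != len(recs):
                raise StackError(
                    f"{path}: {len(pages)} pages for {len(recs)} manifest records"
                )
            depth = _bit_depth_of(pages)
            for rec, page in zip(recs, pages):
                channels[rec.channel] = page.astype(float) / float(2**depth - 1)
                depths.add(depth)
                if rec.treatment is not None:
                    treatment = rec.treatment
        else:
            rec = recs[0]
            arr, depth = read_channel_image(rec.path)
            channels[rec.channel] = arr
            depths.add(depth)
            if rec.treatment is not None:
                treatment = rec.treatment
    shapes = {a.shape for a in channels.values()}
    if len(shapes) > 1:
        raise StackError(
            f"plant {plant_id!r} at {timepoint!r}: channel dimensions "
            f"disagree: {sorted(shapes)}"
        )
    if len(depths) > 1:
        raise StackError(
            f"plant {plant_id!r} at {timepoint!r}: mixed bit depths {sorted(depths)}"
        )
    return SpectralStack(
        channels=channels,
        plant_id=plant_id,
        timepoint=timepoint,
        treatment=treatment,
        bit_depth_in=depths.pop(),
    )


def write_channel_image(path: str | Path, values: np.ndarray, bit_depth: int = 8) -> None:
    """Quantize a [0, 1] float raster to ``bit_depth`` and write PNG/TIFF."""
    if bit_depth not in (8, 16):
        raise ChannelError(f"bit depth must be 8 or 16, got {bit_depth}")
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantized = np.clip(np.rint(np.asarray(values, dtype=float) * scale), 0, scale)
    iio.imwrite(Path(path), quantized.astype(dtype))


#: Stable column order of the per-plant summary CSV.
SUMMARY_COLUMNS = (
    "plant_id",
    "timepoint",
    "treatment",
    "canopy_size_px",
    "ndvi_mean",
    "ndvi_sd",
    "aci_mean",
    "aci_sd",
    "chlf_mean",
)


def write_summaries(summaries: list, path: str | Path) -> None:
    """Write per-plant canopy summaries as CSV, one row per (plant, timepoint).

    Floats are rendered with enough digits to round-trip to 6 significant
    digits; undefined statistics (empty mask) are written as empty fields.
    """
    if not summaries:
        raise ValueError("write_summaries needs a non-empty list of summaries")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for s in summaries:
            row = []
            for col in SUMMARY_COLUMNS:
                value = getattr(s, col)
                if value is None:
                    row.append("")
                elif isinstance(value, float):
                    row.append(f"{value:.9g}")
                else:
                    row.append(value)
            writer.writerow(row)


def read_summaries(path: str | Path):
    """Round-trip reader for the summary CSV; returns a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path)
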