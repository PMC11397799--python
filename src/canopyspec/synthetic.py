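"""Synthetic multispectral plant scenes with full ground truth.

No public image archive exists for the pipeline's source hardware, so
every stage is validated against generated scenes where the truth is known
by construction: the canopy is a union of ellipses (analytic geometry
beats plant-realistic texture for code verification), each channel gets a
flat canopy and background intensity, Gaussian sensor noise is added and
clipped, the NIR channel is resampled by a known injected shift or affine
(emulating the hardware's misaligned infrared path), and only then is
everything quantized to the target bit depth — so the injected transform
is exactly what registration must recover.

A scene's :class:`GroundTruth` carries the pre-misalignment mask, its
pixel count, the noise-free index values implied by the band intensities,
and the injected transform.

:func:`generate_experiment` emulates a dose-response trial: one scene per
(treatment level, replicate), with canopy radius and band values driven by
a response function plus replicate-level jitter, and the true quadratic
dose-response coefficients emitted for recovery tests.  The default
experiment geometry follows a fertilizer-rate design: 6 levels
(0, 0.5, 1, 2, 4, 8 g/pot) x 8 replicates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .errors import SceneSpecError
from .registration import RegistrationTransform
from .stack import CHANNEL_LABELS, SpectralStack

#: Flat band intensities of a healthy canopy (normalized DN); chosen so the
#: implied NDVI (0.68) and fluorescence contrast resemble a well-fertilized
#: plant against a dark soil/substrate background.
DEFAULT_BAND_VALUES: dict[str, float] = {
    "red": 0.15,
    "green": 0.35,
    "blue": 0.10,
    "nir": 0.80,
    "chlf": 0.70,
}

DEFAULT_BACKGROUND_VALUES: dict[str, float] = {
    "red": 0.08,
    "green": 0.08,
    "blue": 0.08,
    "nir": 0.10,
    "chlf": 0.03,
}

#: Fertilizer rates (g per pot) of the emulated dose-response design.
FERTILIZER_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_REPLICATES = 8


@dataclass(frozen=True)
class Ellipse:
    """One canopy blob: center (row, col), semi-axes in px, rotation in rad."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float
    rotation: float = 0.0


@dataclass
class SyntheticSceneSpec:
    """Everything needed to deterministically generate one scene."""

    height: int = 128
    width: int = 128
    canopy: list[Ellipse] = field(
        default_factory=lambda: [Ellipse(64.0, 64.0, 40.0, 40.0)]
    )
    band_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_VALUES)
    )
    background_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_VALUES)
    )
    noise_sd: float = 0.01
    nir_shift: tuple[float, float] = (0.0, 0.0)
    nir_affine: np.ndarray | None = None
    bit_depth: int = 8
    seed: int = 0
    plant_id: str = "synthetic"
    timepoint: str = "t0"
    treatment: float | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise SceneSpecError("bit_depth must be 8 or 16")
        if self.noise_sd < 0:
            raise SceneSpecError("noise_sd must be non-negative")
        for mapping, what in (
            (self.band_values, "band"),
            (self.background_values, "background"),
        ):
            for name, v in mapping.items():
                if name not in CHANNEL_LABELS:
                    raise SceneSpecError(f"unknown channel {name!r} in {what} values")
                if not 0.0 <= v <= 1.0:
                    raise SceneSpecError(f"{what} value for {name!r} outside [0, 1]")
        missing = [c for c in self.band_values if c not in self.background_values]
        if missing:
            raise SceneSpecError(f"background values missing for channels {missing}")
        if self.nir_affine is not None:
            self.nir_affine = np.asarray(self.nir_affine, dtype=float)
            if self.nir_affine.shape != (2, 3):
                raise SceneSpecError("nir_affine must be a 2x3 matrix")


@dataclass
class GroundTruth:
    """What the pipeline should recover from a scene."""

    mask: np.ndarray
    canopy_size_px: int
    true_index_values: dict[str, float]
    injected_transform: RegistrationTransform


def rasterize_ellipses(
    ellipses: list[Ellipse], height: int, width: int
) -> np.ndarray:
    """Boolean union of ellipse interiors on the pixel grid.

    A pixel (r, c) is inside when the rotated, normalized quadratic form
    is <= 1 at the pixel center.
    """
    rows, cols = np.mgrid[0:height, 0:width].astype(float)
    mask = np.zeros((height, width), dtype=bool)
    for e in ellipses:
        dr = rows - e.center_row
        dc = cols - e.center_col
        cr, sr = np.cos(e.rotation), np.sin(e.rotation)
        u = cr * dr + sr * dc
        v = -sr * dr + cr * dc
        mask |= (u / e.semi_row) ** 2 + (v / e.semi_col) ** 2 <= 1.0
    return mask


def scattered_canopy(
    height: int, width: int, n_blobs: int = 80, seed: int = 0
) -> list[Ellipse]:
    """Many small ellipses scattered over the frame.

    Emulates a trailing plant whose shoots cover the whole field of view.
    Unlike a single central disk, this leaves usable texture in every
    registration tile, which is what the affine model needs.
    """
    rng = np.random.default_rng(seed)
    margin = 15.0
    return [
        Ellipse(
            center_row=float(rng.uniform(margin, height - margin)),
            center_col=float(rng.uniform(margin, width - margin)),
            semi_row=float(rng.uniform(5.0, 14.0)),
            semi_col=float(rng.uniform(5.0, 14.0)),
            rotation=float(rng.uniform(0.0, np.pi)),
        )
        for _ in range(n_blobs)
    ]


def _invert_affine(matrix: np.ndarray) -> np.ndarray:
    a = matrix[:, :2]
    t = matrix[:, 2]
    ainv = np.linalg.inv(a)
    return np.column_stack([ainv, -ainv @ t])


def _quantize(arr: np.ndarray, bit_depth: int) -> np.ndarray:
    scale = 2**bit_depth - 1
    return np.rint(np.clip(arr, 0.0, 1.0) * scale) / scale


def true_index_values(band_values: dict[str, float]) -> dict[str, float]:
    """Noise-free index values implied by flat canopy band intensities."""
    out: dict[str, float] = {}
    nir, red, green = (
        band_values.get("nir"),
        band_values.get("red"),
        band_values.get("green"),
    )
    if nir is not None and red is not None and (nir + red) > 0:
        out["NDVI"] = (nir - red) / (nir + red)
    if red is not None and green:
        out["ACI"] = red / green
    return out


def generate_scene(spec: SyntheticSceneSpec) -> tuple[SpectralStack, GroundTruth]:
    """Render one deterministic scene and its ground truth.

    Per channel: canopy pixels take the band value, background pixels the
    background value; Gaussian noise of ``noise_sd`` is added and clipped
    to [0, 1].  The NIR channel is then displaced by ``nir_shift`` (or
    warped by ``nir_affine``) with bilinear resampling and background fill,
    and every channel is quantized to ``bit_depth``.  The ground-truth
    mask reflects the pre-misalignment geometry.
    """
    rng = np.random.default_rng(spec.seed)
    mask = rasterize_ellipses(spec.canopy, spec.height, spec.width)

    channels: dict[str, np.ndarray] = {}
    # Channel order fixed by CHANNEL_LABELS so the RNG stream is stable
    # regardless of dict insertion order.
    for name in CHANNEL_LABELS:
        if name not in spec.band_values:
            continue
        bg = spec.background_values[name]
        img = np.where(mask, spec.band_values[name], bg)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        channels[name] = img

    if spec.nir_affine is not None:
        injected = RegistrationTransform(
            dy=float(spec.nir_affine[0, 2]),
            dx=float(spec.nir_affine[1, 2]),
            matrix=np.asarray(spec.nir_affine, dtype=float),
            moving_channel="nir",
        )
    else:
        injected = RegistrationTransform(
            dy=float(spec.nir_shift[0]),
            dx=float(spec.nir_shift[1]),
            moving_channel="nir",
        )

    if "nir" in channels and not injected.is_identity:
        bg_nir = spec.background_values["nir"]
        if injected.matrix is not None:
            # moving(q) = nir(T^-1(q)): content at reference coordinate p
            # lands at T(p) in the moving frame.
            inv = _invert_affine(injected.matrix)
            rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
            src_r = inv[0, 0] * rows + inv[0, 1] * cols + inv[0, 2]
            src_c = inv[1, 0] * rows + inv[1, 1] * cols + inv[1, 2]
            channels["nir"] = ndi.map_coordinates(
                channels["nir"], [src_r, src_c], order=1, mode="constant", cval=bg_nir
            )
        else:
            channels["nir"] = ndi.shift(
                channels["nir"],
                (injected.dy, injected.dx),
                order=1,
                mode="constant",
                cval=bg_nir,
            )
        channels["nir"] = np.clip(channels["nir"], 0.0, 1.0)

    channels = {k: _quantize(v, spec.bit_depth) for k, v in channels.items()}

    stack = SpectralStack(
        channels=channels,
        plant_id=spec.plant_id,
        timepoint=spec.timepoint,
        treatment=spec.treatment,
        bit_depth_in=spec.bit_depth,
    )
    truth = GroundTruth(
        mask=mask,
        canopy_size_px=int(mask.sum()),
        true_index_values=true_index_values(spec.band_values),
        injected_transform=injected,
    )
    return stack, truth


def bands_for_ndvi(
    target_ndvi: float, band_sum: float = 0.9, base: dict[str, float] | None = None
) -> dict[str, float]:
    """Band values whose implied NDVI equals ``target_ndvi`` exactly.

    Holds nir + red fixed at ``band_sum`` and solves the two-band system;
    other channels come from ``base`` (default canopy values).
    """
    if not -1.0 < target_ndvi < 1.0:
        raise SceneSpecError("target NDVI must lie in (-1, 1)")
    values = dict(base or DEFAULT_BAND_VALUES)
    values["nir"] = band_sum * (1.0 + target_ndvi) / 2.0
    values["red"] = band_sum * (1.0 - target_ndvi) / 2.0
    return values


@dataclass
class DoseResponse:
    """Quadratic treatment response driving the synthetic experiment.

    ``ndvi(x) = ndvi_b0 + ndvi_b1 x + ndvi_b2 x^2`` and
    ``radius(x) = radius_b0 + radius_b1 x + radius_b2 x^2`` (pixels).
    The defaults rise steeply at low rates and saturate at the highest,
    the canonical shape of a fertilizer response.
    """

    ndvi_b0: float = 0.40
    ndvi_b1: float = 0.06
    ndvi_b2: float = -0.0045
    radius_b0: float = 18.0
    radius_b1: float = 3.0
    radius_b2: float = -0.15

    def ndvi(self, level: float) -> float:
        return self.ndvi_b0 + self.ndvi_b1 * level + self.ndvi_b2 * level**2

    def radius(self, level: float) -> float:
        return self.radius_b0 + self.radius_b1 * level + self.radius_b2 * level**2

    def coefficients(self, metric: str) -> tuple[float, float, float]:
        if metric == "ndvi_mean":
            return (self.ndvi_b0, self.ndvi_b1, self.ndvi_b2)
        if metric == "radius":
            return (self.radius_b0, self.radius_b1, self.radius_b2)
        raise KeyError(metric)


@dataclass
class SyntheticExperiment:
    """Scenes plus the truth needed for recovery tests."""

    scenes: list[tuple[SpectralStack, GroundTruth]]
    response: DoseResponse
    levels: tuple[float, ...]
    reps: int


def generate_experiment(
    levels=FERTILIZER_LEVELS,
    reps: int = DEFAULT_REPLICATES,
    response: DoseResponse | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    height: int = 128,
    width: int = 128,
    ndvi_jitter_sd: float = 0.02,
    radius_jitter_sd: float = 1.5,
    nir_shift: tuple[float, float] = (3.0, -5.0),
    bit_depth: int = 8,
) -> SyntheticExperiment:
    """One scene per (treatment level, replicate) with a known dose response.

    Replicate-level jitter (Gaussian, SDs ``ndvi_jitter_sd`` on the target
    NDVI and ``radius_jitter_sd`` px on the canopy radius) gives the
    dose-response recovery a controlled noise floor on top of the per-pixel
    sensor noise.  Each scene's NIR channel carries the same injected
    misalignment so the end-to-end pipeline must register before NDVI.
    """
    if reps < 1:
        raise SceneSpecError("reps must be >= 1")
    response = response or DoseResponse()
    rng = np.random.default_rng(seed)
    scenes: list[tuple[SpectralStack, GroundTruth]] = []
    for level in levels:
        for rep in range(reps):
            target = response.ndvi(level) + rng.normal(0.0, ndvi_jitter_sd)
            target = float(np.clip(target, -0.95, 0.95))
            radius = response.radius(level) + rng.normal(0.0, radius_jitter_sd)
            radius = float(max(radius, 4.0))
            spec = SyntheticSceneSpec(
                height=height,
                width=width,
                canopy=[Ellipse(height / 2.0, width / 2.0, radius, radius)],
                band_values=bands_for_ndvi(target),
                noise_sd=noise_sd,
                nir_shift=nir_shift,
                bit_depth=bit_depth,
                seed=int(rng.integers(0, 2**31 - 1)),
                plant_id=f"L{level:g}_r{rep}",
                timepoint="t0",
                treatment=float(level),
            )
            scenes.append(generate_scene(spec))
    return SyntheticExperiment(
        scenes=scenes, response=response, levels=tuple(levels), reps=reps
    )


def write_scene(
    stack: SpectralStack,
    out_dir: str | Path,
    manifest_rows: list[dict] | None = None,
) -> list[dict]:
    """Write one scene's channels as PNGs and return its manifest rows."""
    from .spectral_io import write_channel_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = manifest_rows if manifest_rows is not None else []
    for name, values in stack.channels.items():
        fname = f"{stack.plant_id}_{stack.timepoint}_{name}.png"
        write_channel_image(out_dir / fname, values, bit_depth=stack.bit_depth_in)
        rows.append(
            {
                "plant_id": stack.plant_id,
                "timepoint": stack.timepoint,
                "treatment": "" if stack.treatment is None else f"{stack.treatment:g}",
                "channel": name,
                "file": fname,
            }
        )
    return rows


def write_manifest(rows: list[dict], path: str | Path) -> None:
    from .spectral_io import MANIFEST_COLUMNS

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
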