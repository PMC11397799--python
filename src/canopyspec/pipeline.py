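"""End-to-end per-plant analysis: register -> mask -> indices -> summary."""

from __future__ import annotations

from dataclasses import dataclass

from .indices import DEFAULT_ACI_FORMULA, IndexMap, compute_aci, compute_ndvi
from .registration import RegistrationTransform, register_stack
from .segmentation import PlantMask, SegmentationParams, compute_mask
from .stack import SpectralStack
from .summary_viz import CanopySummary, summarize_plant


@dataclass
class PlantAnalysis:
    """Everything produced for one plant at one timepoint."""

    summary: CanopySummary
    mask: PlantMask
    maps: list[IndexMap]
    transform: RegistrationTransform
    stack: SpectralStack


def analyze_stack(
    stack: SpectralStack,
    register: str = "shift",
    seg_params: SegmentationParams | None = None,
    indices: tuple[str, ...] = ("ndvi", "aci"),
    aci_formula: str = DEFAULT_ACI_FORMULA,
    register_upsample: int = 20,
    register_reference: str = "red",
) -> PlantAnalysis:
    """Run the full single-plant pipeline on an in-memory stack.

    Registration (NIR onto the reference channel) runs first so the mask
    and all index maps share one frame; the mask comes from the
    fluorescence channel; indices are evaluated per pixel over the mask;
    the summary collapses everything to scalars.
    """
    registered, transform = register_stack(
        stack,
        mode=register,
        reference=register_reference,
        upsample=register_upsample,
    )
    mask = compute_mask(registered, seg_params)
    maps: list[IndexMap] = []
    for index in indices:
        if index == "ndvi":
            maps.append(compute_ndvi(registered, mask))
        elif index == "aci":
            maps.append(compute_aci(registered, mask, formula=aci_formula))
        else:
            raise ValueError(f"unknown index {index!r}")
    summary = summarize_plant(registered, mask, maps)
    return PlantAnalysis(
        summary=summary, mask=mask, maps=maps, transform=transform, stack=registered
    )
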