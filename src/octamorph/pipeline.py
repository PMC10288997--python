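"""End-to-end per-eye processing: image -> masks -> metrics -> sectors."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import EnFaceImage, FazRegion, VesselMask
from .etdrs import EtdrsGrid, build_grid, sector_metrics
from .morphometrics import compute_metric_vector
from .segmentation import SegmentationParams, segment, segment_faz
from .vessel_graph import analyze_mask


@dataclass
class EyeAnalysis:
    vessels: VesselMask
    faz: FazRegion
    grid: EtdrsGrid
    metrics: dict[str, float]
    sectors: dict[str, dict[str, float]]


def analyze_eye(
    image: EnFaceImage,
    vessels: Optional[VesselMask] = None,
    faz: Optional[FazRegion] = None,
    seg_params: Optional[SegmentationParams] = None,
    metric_kwargs: Optional[dict] = None,
    grid_center: Optional[tuple[float, float]] = None,
    base_diameter_mm: float = 0.75,
) -> EyeAnalysis:
    """Analyze one en-face angiogram.

    Precomputed masks bypass segmentation entirely, so morphometry can be
    validated independently of segmentation fidelity.  The ETDRS grid is
    centered on the FAZ centroid, falling back to the image center when
    the FAZ is degenerate.
    """
    if vessels is None:
        vessels, seg_faz, _ = segment(image, seg_params)
        faz = faz if faz is not None else seg_faz
    elif faz is None:
        faz = segment_faz(vessels, seg_params)

    graph = analyze_mask(vessels.pixels)
    metrics = compute_metric_vector(
        vessels, faz=faz, image=image.pixels, graph=graph, **(metric_kwargs or {})
    )

    if grid_center is None:
        if faz.degenerate or faz.area_px == 0:
            grid_center = ((image.width - 1) / 2.0, (image.width - 1) / 2.0)
        else:
            grid_center = faz.centroid_px
    grid = build_grid(
        grid_center,
        image.pixel_size_mm,
        image.laterality,
        vessels.pixels.shape,
        base_diameter_mm=base_diameter_mm,
    )
    sectors = sector_metrics(vessels.pixels, graph, grid)
    return EyeAnalysis(vessels=vessels, faz=faz, grid=grid, metrics=metrics, sectors=sectors)
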