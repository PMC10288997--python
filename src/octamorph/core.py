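"""Core data model for en-face OCTA morphometry.

An OCTA acquisition exports one en-face angiogram per retinal capillary
plexus (superficial, intermediate, deep vascular complex) per eye, on a
square field of view centered on the fovea.  All downstream morphometry
derives from two binary segmentations of that angiogram: the vessel mask
and the foveal avascular zone (FAZ).

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, row 0 at the superior
  (top) edge of the image;
* physical conversions always go through ``pixel_size_mm``;
* intensities are min-max normalized to ``[0, 1]`` per image.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Default acquisition geometry: 3 x 3 mm field of view, 304 x 304 pixels.
DEFAULT_FOV_MM = 3.0
DEFAULT_IMAGE_SIZE = 304

#: The 12 biomarkers, in canonical reporting order.
METRIC_NAMES = (
    "FA",
    "FC",
    "FAR",
    "FR",
    "FS",
    "direction_area",
    "direction_ratio",
    "tortuosity",
    "VAD",
    "VLD",
    "FD",
    "B_num",
)

#: Sub-regional metrics computed per ETDRS sector.
SECTOR_METRIC_NAMES = ("VAD", "VLD", "FD", "tortuosity", "B_num")


class Plexus(str, enum.Enum):
    """Depth-resolved capillary plexus of an en-face export."""

    SVC = "SVC"
    IVC = "IVC"
    DVC = "DVC"


class Laterality(str, enum.Enum):
    """Eye side; determines which side of the macular grid is temporal."""

    OD = "OD"  # right eye, temporal on the image left
    OS = "OS"  # left eye, temporal on the image right


class Group(str, enum.Enum):
    """Study arm of an eye."""

    HC = "HC"
    ON = "ON"
    NON_ON = "NON_ON"


@dataclass
class EnFaceImage:
    """One plexus-resolved grayscale angiogram with its physical scale."""

    pixels: np.ndarray
    plexus: Plexus
    laterality: Laterality
    fov_mm: float = DEFAULT_FOV_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h != w:
            raise ValueError(f"en-face image must be square, got shape {h}x{w}")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]; normalize on read")
        self.plexus = Plexus(self.plexus)
        self.laterality = Laterality(self.laterality)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_size_mm(self) -> float:
        return self.fov_mm / self.width


@dataclass
class VesselMask:
    """Binary vessel segmentation, aligned with its source image."""

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_FOV_MM / DEFAULT_IMAGE_SIZE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("vessel mask must be 2-D")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class FazRegion:
    """The foveal avascular zone: one connected avascular component.

    ``boundary`` is a closed contour as an (n, 2) float array of
    ``(row, col)`` vertices.  ``degenerate`` flags the vessel-free case
    where the whole image is avascular; ``clipped`` flags a region
    touching the image border.
    """

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_FOV_MM / DEFAULT_IMAGE_SIZE
    boundary: Optional[np.ndarray] = None
    degenerate: bool = False
    clipped: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("FAZ mask must be 2-D")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def centroid_px(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.pixels)
        if rr.size == 0:
            raise ValueError("empty FAZ region has no centroid")
        return float(rr.mean()), float(cc.mean())


@dataclass
class EyeRecord:
    """Per-eye study record: identity, covariates and computed metrics.

    ``metrics`` maps plexus name -> region name -> metric name -> value,
    region ``"full"`` being the whole analyzed field.
    """

    subject_id: str
    eye: Laterality
    group: Group
    age: float
    bmi: float = float("nan")
    bcva: float = float("nan")
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eye = Laterality(self.eye)
        self.group = Group(self.group)
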