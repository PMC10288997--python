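"""ETDRS macular grid and sub-regional metric extraction.

The grid is a central circle of diameter R = 0.75 mm around the foveal
center plus an internal ring (diameter 2R) and an external ring (3R),
each split by the two 45-degree diagonals into superior, temporal,
inferior and nasal quadrants — eight sectors named SI, TI, II, NI, SE,
TE, IE, NE.  Temporal is the image-left side for a right eye (OD) and
image-right for a left eye (OS); nasal is the opposite side.  The
central circle is its own region ``C`` and is excluded from the eight
sectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SECTOR_METRIC_NAMES, Laterality
from .morphometrics import fractal_dimension, vessel_densities
from .vessel_graph import SkeletonGraph, tortuosity

SECTOR_NAMES = ("SI", "TI", "II", "NI", "SE", "TE", "IE", "NE")
REGION_NAMES = ("C",) + SECTOR_NAMES


@dataclass
class EtdrsGrid:
    """Rasterized grid: 9 pairwise-disjoint boolean sector masks."""

    center_px: tuple[float, float]
    base_diameter_mm: float
    pixel_size_mm: float
    laterality: Laterality
    sector_masks: dict[str, np.ndarray]

    @property
    def ring_diameters_mm(self) -> tuple[float, float, float]:
        r = self.base_diameter_mm
        return (r, 2 * r, 3 * r)

    def annulus(self, which: str) -> np.ndarray:
        """Union of the 4 internal ('internal') or external sectors."""
        names = [s for s in SECTOR_NAMES if s.endswith("I" if which == "internal" else "E")]
        out = np.zeros_like(self.sector_masks["C"])
        for s in names:
            out |= self.sector_masks[s]
        return out


def build_grid(
    center_px: tuple[float, float],
    pixel_size_mm: float,
    laterality: Laterality | str,
    image_shape: tuple[int, int],
    base_diameter_mm: float = 0.75,
) -> EtdrsGrid:
    """Rasterize the grid centered on ``center_px`` (usually the FAZ centroid).

    Radial boundaries at base_diameter/2, base_diameter and
    1.5 * base_diameter (in mm); quadrants bounded by the two diagonals
    through the center, with diagonal pixels assigned to the
    superior/inferior sectors so the OD and OS partitions are exact
    mirror images.  Rejects grids overhanging the image.
    """
    laterality = Laterality(laterality)
    h, w = image_shape
    r_outer_mm = 1.5 * base_diameter_mm
    r_outer_px = r_outer_mm / pixel_size_mm
    for dim, coord in ((h, center_px[0]), (w, center_px[1])):
        over = max(r_outer_px - coord, coord + r_outer_px - (dim - 1)) * pixel_size_mm
        if over > 0:
            raise ValueError(
                f"ETDRS grid exceeds the image bounds by {over:.3f} mm; "
                f"outer radius {r_outer_mm} mm around center {center_px}"
            )
    rows = np.arange(h)[:, None] - center_px[0]
    cols = np.arange(w)[None, :] - center_px[1]
    rho_mm = np.hypot(rows, cols) * pixel_size_mm

    central = rho_mm <= base_diameter_mm / 2.0
    internal = (rho_mm > base_diameter_mm / 2.0) & (rho_mm <= base_diameter_mm)
    external = (rho_mm > base_diameter_mm) & (rho_mm <= r_outer_mm)

    # angle measured with y up (superior at the top of the image); pixels on
    # the diagonals go to the superior/inferior sectors (closed), keeping the
    # partition exactly mirror-symmetric between OD and OS
    ang = np.degrees(np.arctan2(-rows, cols))  # (-180, 180], 0 = image right
    superior = (ang >= 45.0) & (ang <= 135.0)
    left = (ang > 135.0) | (ang < -135.0)
    inferior = (ang >= -135.0) & (ang <= -45.0)
    right = (ang > -45.0) & (ang < 45.0)
    temporal, nasal = (left, right) if laterality is Laterality.OD else (right, left)

    quads = {"S": superior, "T": temporal, "I": inferior, "N": nasal}
    masks: dict[str, np.ndarray] = {"C": central}
    for qname, qmask in quads.items():
        masks[f"{qname}I"] = internal & qmask
        masks[f"{qname}E"] = external & qmask
    return EtdrsGrid(
        center_px=tuple(center_px),
        base_diameter_mm=base_diameter_mm,
        pixel_size_mm=pixel_size_mm,
        laterality=laterality,
        sector_masks=masks,
    )


def sector_metrics(
    mask: np.ndarray,
    graph: SkeletonGraph,
    grid: EtdrsGrid,
    box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32),
    tortuosity_weighting: str = "length",
) -> dict[str, dict[str, float]]:
    """Five sub-regional metrics per sector: VAD, VLD, FD, tortuosity, B-num.

    B-num counts bifurcation nodes whose coordinates fall in the sector;
    tortuosity averages branches whose midpoint falls in the sector; FD
    box-counts the sector-restricted foreground on the sector's bounding
    box.  Sectors without skeleton pixels report VLD = 0 and NaN for FD
    and tortuosity.
    """
    mask = np.asarray(mask).astype(bool)
    out: dict[str, dict[str, float]] = {}
    nodes = graph.bifurcations
    for name in SECTOR_NAMES:
        sector = grid.sector_masks[name]
        vad, vld = vessel_densities(mask, graph.skeleton, sector)
        m: dict[str, float] = {"VAD": vad, "VLD": vld}

        inside = 0
        for r, c in nodes:
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < sector.shape[0] and 0 <= ci < sector.shape[1] and sector[ri, ci]:
                inside += 1
        m["B_num"] = float(inside)

        sel = [b for b in graph.branches if sector[b.midpoint]]
        try:
            m["tortuosity"] = tortuosity(sel, weighting=tortuosity_weighting)
        except ValueError:
            m["tortuosity"] = float("nan")

        cropped = mask & sector
        if cropped.any():
            rr, cc = np.nonzero(sector)
            window = cropped[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
            try:
                m["FD"] = fractal_dimension(window, box_sizes=box_sizes)
            except ValueError:
                m["FD"] = float("nan")
        else:
            m["FD"] = float("nan")
        out[name] = m
    assert set(m) == set(SECTOR_METRIC_NAMES)
    return out
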