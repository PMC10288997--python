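"""Synthetic angiogram and cohort generators with exact ground truth.

Real OCTA angiograms for this kind of study are patient data and are not
redistributable, so every downstream stage is exercised on two kinds of
synthetic input instead:

* vascular images: stochastic branching trees grown from the image border
  toward the fovea around a noise-perturbed elliptical avascular zone.
  The grower is a discrete random walk with per-step bifurcation, not a
  physiological angiogenesis model — its point is exact bookkeeping: every
  centerline polyline, split event, and branch arc/chord length is
  recorded during growth, so skeleton- and mask-based estimators can be
  validated against exact ground truth;
* metric cohorts: independent Gaussian draws per eye and biomarker from
  published group means/SDs (see :mod:`octamorph.presets`).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk, remove_small_holes

from .core import DEFAULT_FOV_MM, DEFAULT_IMAGE_SIZE, EnFaceImage, FazRegion, Laterality, Plexus, VesselMask
from .presets import COHORT_PRESETS


# ---------------------------------------------------------------------------
# FAZ shapes

@dataclass
class FazShapeParams:
    """Noise-perturbed ellipse standing in for a foveal avascular zone."""

    area_mm2: float = 0.3
    axial_ratio: float = 1.0
    boundary_noise: float = 0.05  # radial perturbation, fraction of local radius
    n_vertices: int = 256
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")
        if self.axial_ratio < 1:
            raise ValueError("axial_ratio must be >= 1")
        if not 0 <= self.boundary_noise < 0.5:
            raise ValueError("boundary_noise must lie in [0, 0.5)")
        if self.n_vertices < 8:
            raise ValueError("n_vertices must be >= 8")


def faz_polygon(
    params: FazShapeParams,
    pixel_size_mm: float,
    center_px: tuple[float, float],
) -> np.ndarray:
    """Vertex list (n, 2) of (row, col) for the perturbed ellipse, in pixels.

    The radial perturbation is a band-limited periodic signal (harmonics
    2..6) so the boundary stays smooth and free of self-intersections for
    ``boundary_noise < 0.5``.
    """
    rng = np.random.default_rng(params.seed)
    area_px = params.area_mm2 / pixel_size_mm**2
    # pi * a * b = area, a / b = axial_ratio
    b = math.sqrt(area_px / (math.pi * params.axial_ratio))
    a = b * params.axial_ratio
    theta = np.linspace(0.0, 2 * math.pi, params.n_vertices, endpoint=False)
    radius = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if params.boundary_noise > 0:
        wobble = np.zeros_like(theta)
        for k in range(2, 7):
            wobble += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
        wobble /= max(np.abs(wobble).max(), 1e-12)
        radius = radius * (1.0 + params.boundary_noise * wobble)
    phi = math.radians(params.rotation_deg)
    x = radius * np.cos(theta + phi)
    y = radius * np.sin(theta + phi)
    rows = center_px[0] + y
    cols = center_px[1] + x
    return np.column_stack([rows, cols])


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from the shoelace formula (vertices as (row, col))."""
    r = vertices[:, 0]
    c = vertices[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


def polygon_perimeter_length(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def generate_faz_shape(
    params: FazShapeParams,
    pixel_size_mm: float = DEFAULT_FOV_MM / DEFAULT_IMAGE_SIZE,
    image_size: int = DEFAULT_IMAGE_SIZE,
    center_px: Optional[tuple[float, float]] = None,
) -> tuple[FazRegion, float, float]:
    """Rasterize a synthetic FAZ; returns (region, analytic area, analytic perimeter).

    Analytic values are in mm^2 / mm, computed on the generating polygon
    (shoelace area, summed edge lengths) before rasterization.
    """
    if center_px is None:
        center_px = ((image_size - 1) / 2.0, (image_size - 1) / 2.0)
    verts = faz_polygon(params, pixel_size_mm, center_px)
    area_px = shoelace_area(verts)
    if area_px < 1.0:
        raise ValueError("degenerate FAZ polygon: area below one pixel")
    if verts[:, 0].min() < 0 or verts[:, 1].min() < 0 or verts.max() >= image_size:
        raise ValueError("FAZ polygon does not fit inside the image")
    mask = np.zeros((image_size, image_size), dtype=bool)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=mask.shape)
    mask[rr, cc] = True
    region = FazRegion(pixels=mask, pixel_size_mm=pixel_size_mm, boundary=verts)
    return region, area_px * pixel_size_mm**2, polygon_perimeter_length(verts) * pixel_size_mm


# ---------------------------------------------------------------------------
# Vessel trees

@dataclass
class TreeParams:
    """Growth parameters for the stochastic branching tree generator."""

    n_roots: int = 22
    branch_prob: float = 0.05  # per growth step
    step_px: float = 3.0
    angle_sigma_deg: float = 8.0
    bifurcation_angle_deg: float = 35.0  # mean split half-angle
    vessel_width_px: int = 2  # rasterization (dilation) radius
    image_size: int = DEFAULT_IMAGE_SIZE
    fov_mm: float = DEFAULT_FOV_MM
    min_branch_px: float = 10.0  # a child must reach this arc or the split is rolled back
    min_junction_sep_px: float = 5.0
    # centerlines never approach closer than this; None = 2 * width + 3, the
    # smallest gap at which dilated vessels remain visually distinct
    clearance_px: Optional[float] = None
    max_branch_arc_px: float = 400.0
    # per-step pull of the heading toward the image center (fraction of the
    # angular error); emulates the centripetal course of macular vessels and
    # makes the grown trees actually ring the avascular zone
    center_bias: float = 0.2
    # terminal capillary arcade delimiting the FAZ, as in real maculae; a
    # closed centerline loop just outside the FAZ polygon
    faz_ring: bool = True
    speckle_sigma: float = 0.15
    background_ramp: float = 0.1
    faz: FazShapeParams = field(default_factory=FazShapeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1 or self.step_px <= 0 or self.vessel_width_px < 1:
            raise ValueError("n_roots, step_px and vessel_width_px must be positive")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.clearance_px is None:
            self.clearance_px = 2.0 * self.vessel_width_px + 3.0


@dataclass
class Branch:
    """One centerline polyline between two nodes of the grown tree."""

    points: np.ndarray  # (n, 2) float (row, col)
    arc_length_px: float
    chord_length_px: float
    mean_heading_rad: float


@dataclass
class GroundTruth:
    """Exact morphometry recorded while the tree was grown."""

    bifurcation_count: int
    junctions_px: np.ndarray  # (k, 2) float
    branches: list[Branch]
    total_centerline_length_px: float
    vessel_pixel_count: int
    faz_vertices: np.ndarray
    faz_area_mm2: float
    faz_perimeter_mm: float
    faz_axial_ratio: float


class _Canvas:
    """Spatial hash of stamped centerline samples for clearance queries."""

    def __init__(self, cell: float) -> None:
        self.cell = cell
        self.grid: dict[tuple[int, int], list[tuple[float, float, int, int]]] = {}
        self.count = 0

    def _key(self, r: float, c: float) -> tuple[int, int]:
        return (int(r // self.cell), int(c // self.cell))

    def add(self, r: float, c: float, token: int) -> int:
        seq = self.count
        self.grid.setdefault(self._key(r, c), []).append((r, c, token, seq))
        self.count += 1
        return seq

    def remove_token(self, token: int) -> None:
        for key in list(self.grid):
            kept = [p for p in self.grid[key] if p[2] != token]
            if kept:
                self.grid[key] = kept
            else:
                del self.grid[key]

    def too_close(
        self,
        r: float,
        c: float,
        radius: float,
        own_token: int,
        own_min_seq: int,
        guard: Optional[tuple[float, float, float, set]],
    ) -> bool:
        kr, kc = self._key(r, c)
        reach = int(math.ceil(radius / self.cell))
        for dr in range(-reach, reach + 1):
            for dc in range(-reach, reach + 1):
                for pr, pc, token, seq in self.grid.get((kr + dr, kc + dc), ()):
                    if token == own_token and seq >= own_min_seq:
                        continue  # own recent tail
                    if (
                        guard is not None
                        and token in guard[3]  # parent/sibling only: foreign
                        # branches passing near the junction still collide
                        and (pr - guard[0]) ** 2 + (pc - guard[1]) ** 2 <= guard[2] ** 2
                    ):
                        continue
                    if (pr - r) ** 2 + (pc - c) ** 2 < radius**2:
                        return True
        return False


def _segment_samples(p0: np.ndarray, p1: np.ndarray, spacing: float = 0.7) -> np.ndarray:
    n = max(int(math.ceil(np.hypot(*(p1 - p0)) / spacing)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[1:]
    return p0 + t[:, None] * (p1 - p0)


class _TreeGrower:
    def __init__(self, params: TreeParams, rng: np.random.Generator) -> None:
        self.p = params
        self.rng = rng
        self.size = params.image_size
        px = params.fov_mm / params.image_size
        center = ((self.size - 1) / 2.0, (self.size - 1) / 2.0)
        self.faz_verts = faz_polygon(params.faz, px, center)
        self._faz_lut = np.zeros((self.size, self.size), dtype=bool)
        rr, cc = draw_polygon(self.faz_verts[:, 0], self.faz_verts[:, 1], shape=self._faz_lut.shape)
        self._faz_lut[rr, cc] = True
        self.canvas = _Canvas(cell=max(params.clearance_px, 1.0))
        self.branches: list[Branch] = []
        self.junctions: list[np.ndarray] = []
        self._token = 0

    # -- geometry helpers ---------------------------------------------------
    def _in_faz(self, r: float, c: float) -> bool:
        return bool(self._faz_lut[int(round(r)), int(round(c))])

    def _in_bounds(self, r: float, c: float) -> bool:
        m = self.p.vessel_width_px
        return m <= r < self.size - 1 - m and m <= c < self.size - 1 - m

    def _sep_ok(self, pos: np.ndarray) -> bool:
        for j in self.junctions:
            if np.hypot(*(pos - j)) < self.p.min_junction_sep_px:
                return False
        return True

    # -- growth -------------------------------------------------------------
    def _grow_branch(
        self,
        pos: np.ndarray,
        heading: float,
        depth: int,
        guard: Optional[tuple[float, float, float, set]],
    ) -> Optional[Branch]:
        """Grow one branch; recurse on bifurcation.  Returns the committed
        branch, or None if it was rolled back (too short to keep)."""
        p = self.p
        token = self._token
        self._token += 1
        pts = [pos.copy()]
        headings = [heading]
        arc = 0.0
        min_seq = self.canvas.count  # own samples from here on are "recent tail"
        tail_window = int(math.ceil((p.clearance_px + p.step_px) / 0.7)) + 2

        def commit(reason_split: bool) -> Optional[Branch]:
            if not reason_split and arc < p.min_branch_px and depth > 0:
                self.canvas.remove_token(token)
                return None
            points = np.asarray(pts)
            chord = float(np.hypot(*(points[-1] - points[0])))
            # axial circular mean of the per-step headings (orientation mod pi)
            hs = np.asarray(headings)
            mean_heading = 0.5 * math.atan2(
                float(np.mean(np.sin(2 * hs))), float(np.mean(np.cos(2 * hs)))
            ) % math.pi
            br = Branch(points, arc, chord, mean_heading)
            self.branches.append(br)
            return br

        center = np.array([(self.size - 1) / 2.0, (self.size - 1) / 2.0])
        while arc < p.max_branch_arc_px:
            heading = heading + math.radians(self.rng.normal(0.0, p.angle_sigma_deg))
            if p.center_bias > 0:
                to_center = math.atan2(*(center - pos))
                err = (to_center - heading + math.pi) % (2 * math.pi) - math.pi
                heading += p.center_bias * err
            step = np.array([math.sin(heading), math.cos(heading)]) * p.step_px
            new = pos + step
            if not self._in_bounds(*new) or self._in_faz(*new):
                return commit(False)
            samples = _segment_samples(pos, new)
            own_min_seq = max(min_seq, self.canvas.count - tail_window)
            if any(
                self.canvas.too_close(s[0], s[1], p.clearance_px, token, own_min_seq, guard)
                for s in samples
            ):
                return commit(False)
            for s in samples:
                self.canvas.add(s[0], s[1], token)
            pts.append(new.copy())
            headings.append(heading)
            arc += p.step_px
            pos = new
            if (
                arc >= p.min_branch_px
                and self.rng.random() < p.branch_prob
                and self._sep_ok(pos)
            ):
                branch = commit(True)
                assert branch is not None
                self._bifurcate(pos, heading, depth, token)
                return branch
        return commit(False)

    def _bifurcate(self, pos: np.ndarray, heading: float, depth: int, parent_token: int) -> None:
        p = self.p
        marker = pos.copy()
        self.junctions.append(marker)  # descendants may append (and cancel) more
        allowed = {parent_token}
        guard = (pos[0], pos[1], p.clearance_px + 1.0, allowed)
        half = math.radians(p.bifurcation_angle_deg + self.rng.normal(0.0, 5.0))
        kept = 0
        for sign in (-1.0, 1.0):
            child_token = self._token  # assigned inside _grow_branch
            child = self._grow_branch(pos.copy(), heading + sign * half, depth + 1, guard)
            allowed.add(child_token)  # the sibling may share the junction exit
            if child is not None:
                kept += 1
        if kept < 2:
            # a split with fewer than two established arms is not a
            # bifurcation; a lone surviving arm reads as a continuation
            self.junctions = [j for j in self.junctions if j is not marker]

    def _stamp_faz_ring(self) -> None:
        """Closed capillary arcade just outside the FAZ polygon.

        Stamped before tree growth so trunks keep clearance from it; its
        dilation bounds the avascular zone at the polygon boundary.
        """
        offset = self.p.vessel_width_px + 1.0
        centroid = self.faz_verts.mean(axis=0)
        rel = self.faz_verts - centroid
        norm = np.hypot(rel[:, 0], rel[:, 1])
        ring = centroid + rel * ((norm + offset) / norm)[:, None]
        token = self._token
        self._token += 1
        samples = [ring[0]]
        for i in range(len(ring)):
            nxt = ring[(i + 1) % len(ring)]
            samples.extend(_segment_samples(ring[i], nxt))
        for s in samples:
            self.canvas.add(s[0], s[1], token)
        closed = np.vstack([ring, ring[:1]])
        arc = float(np.hypot(*np.diff(closed, axis=0).T).sum())
        self.branches.append(Branch(points=closed, arc_length_px=arc,
                                    chord_length_px=0.0, mean_heading_rad=0.0))

    def grow(self) -> None:
        p = self.p
        size = self.size
        center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
        if p.faz_ring:
            self._stamp_faz_ring()
        margin = p.vessel_width_px + 1
        perim_pos = (np.arange(p.n_roots) + self.rng.uniform(0.2, 0.8, p.n_roots)) / p.n_roots
        for u in perim_pos:
            t = u * 4.0
            side = int(t)
            frac = t - side
            lo, hi = margin, size - 1 - margin
            span = hi - lo
            if side == 0:
                start = np.array([float(lo), lo + frac * span])
            elif side == 1:
                start = np.array([lo + frac * span, float(hi)])
            elif side == 2:
                start = np.array([float(hi), hi - frac * span])
            else:
                start = np.array([hi - frac * span, float(lo)])
            aim = center - start
            heading = math.atan2(aim[0], aim[1]) + math.radians(self.rng.normal(0.0, 12.0))
            self._grow_branch(start, heading, depth=0, guard=None)


def rasterize_centerlines(branches: list[Branch], image_size: int) -> np.ndarray:
    """Boolean image of all branch polylines sampled at sub-pixel spacing."""
    img = np.zeros((image_size, image_size), dtype=bool)
    for br in branches:
        pts = br.points
        for i in range(len(pts) - 1):
            for s in np.vstack([[pts[i]], _segment_samples(pts[i], pts[i + 1], 0.5)]):
                r, c = int(round(s[0])), int(round(s[1]))
                if 0 <= r < image_size and 0 <= c < image_size:
                    img[r, c] = True
    return img


def generate_vessel_tree(
    params: TreeParams,
    plexus: Plexus | str = Plexus.SVC,
    laterality: Laterality | str = Laterality.OD,
) -> tuple[EnFaceImage, VesselMask, GroundTruth]:
    """Grow a synthetic vascular tree; returns (image, mask, ground truth).

    The mask is the dilation of the recorded centerlines by
    ``vessel_width_px``; the image adds multiplicative speckle and a
    linear background ramp.  Identical parameters (including seed) give
    byte-identical outputs.
    """
    px_size = params.fov_mm / params.image_size
    faz_area_px = params.faz.area_mm2 / px_size**2
    if faz_area_px >= params.image_size**2:
        raise ValueError("FAZ polygon larger than the image")
    rng = np.random.default_rng(params.seed)
    grower = _TreeGrower(params, rng)
    grower.grow()

    centerlines = rasterize_centerlines(grower.branches, params.image_size)
    mask_px = dilation(centerlines, disk(params.vessel_width_px))
    # dilation of a polyline cannot have genuine holes; sharp bends may pinch
    # off sub-footprint holes, which would read as spurious skeleton loops
    mask_px = remove_small_holes(mask_px, max_size=4 * params.vessel_width_px**2)
    mask = VesselMask(pixels=mask_px, pixel_size_mm=px_size)

    base = mask_px.astype(float) * 0.8
    speckle = 1.0 + params.speckle_sigma * rng.standard_normal(mask_px.shape)
    ramp = params.background_ramp * (np.arange(params.image_size) / params.image_size)
    img = np.clip(base * speckle + ramp[None, :] + 0.02, 0.0, 1.0)
    img -= img.min()
    if img.max() > 0:
        img /= img.max()
    image = EnFaceImage(pixels=img, plexus=Plexus(plexus), laterality=Laterality(laterality), fov_mm=params.fov_mm)

    total = float(sum(br.arc_length_px for br in grower.branches))
    gt = GroundTruth(
        bifurcation_count=len(grower.junctions),
        junctions_px=np.asarray(grower.junctions).reshape(-1, 2),
        branches=grower.branches,
        total_centerline_length_px=total,
        vessel_pixel_count=int(mask_px.sum()),
        faz_vertices=grower.faz_verts,
        faz_area_mm2=shoelace_area(grower.faz_verts) * px_size**2,
        faz_perimeter_mm=polygon_perimeter_length(grower.faz_verts) * px_size,
        faz_axial_ratio=params.faz.axial_ratio,
    )
    return image, mask, gt


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class GroupSpec:
    """One study arm: sample size and Gaussian (mean, sd) per column."""

    name: str
    n_eyes: int
    metrics: dict[str, tuple[float, float]]
    age: tuple[float, float] = (47.5, 13.0)
    bmi: tuple[float, float] = (22.6, 2.4)
    bcva: tuple[float, float] = (1.0, 0.3)

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("each group needs at least 2 eyes")
        for col, (_, sd) in self.metrics.items():
            if sd < 0:
                raise ValueError(f"negative SD for {col}")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    seed: int = 0


def cohort_spec_from_preset(preset: str, seed: int = 0) -> CohortSpec:
    """Build a CohortSpec from a named published-summary preset."""
    try:
        data = COHORT_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(COHORT_PRESETS)}")
    groups = []
    for name, g in data.items():
        cov = g["covariates"]
        groups.append(
            GroupSpec(
                name=name,
                n_eyes=g["n_eyes"],
                metrics=dict(g["metrics"]),
                age=cov["age"],
                bmi=cov["bmi"],
                bcva=cov["bcva"],
            )
        )
    return CohortSpec(groups=groups, seed=seed)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort: independent Gaussians per eye and column.

    Returns a tidy frame with one row per eye: subject, eye, group,
    age/bmi/bcva covariates, then one column per metric.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in spec.groups:
        n = g.n_eyes
        rows = {
            "subject": [f"{g.name}-{i // 2:03d}" for i in range(n)],
            "eye": [("OD", "OS")[i % 2] for i in range(n)],
            "group": [g.name] * n,
            "age": rng.normal(g.age[0], g.age[1], n),
            "bmi": rng.normal(g.bmi[0], g.bmi[1], n),
            "bcva": rng.normal(g.bcva[0], g.bcva[1], n),
        }
        for col, (mean, sd) in g.metrics.items():
            rows[col] = rng.normal(mean, sd, n)
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
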