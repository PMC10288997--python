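import math

import numpy as np
import pytest
from skimage.morphology import dilation, disk

from octamorph.core import FazRegion, VesselMask
from octamorph.morphometrics import (
    DirectionEllipse,
    OrientationField,
    compute_metric_vector,
    direction_ellipse,
    faz_shape_metrics,
    fractal_dimension,
    orientation_field,
    vessel_densities,
)
from octamorph.vessel_graph import analyze_mask


def _disk_region(r=50, pad=5):
    return FazRegion(pixels=np.pad(disk(r), pad))


def _sierpinski(depth=5):
    m = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m, m], [m, z, m], [m, m, m]])
    return m


class TestFazShape:
    def test_circle(self):
        m = faz_shape_metrics(_disk_region())
        assert 0.98 <= m.FC <= 1.0
        assert 1.0 <= m.FAR <= 1.02
        assert m.FS >= 0.98
        assert m.FR == pytest.approx(1.0, abs=0.02)

    def test_square_circularity(self):
        sq = np.zeros((120, 120), dtype=bool)
        sq[10:90, 10:90] = True
        m = faz_shape_metrics(FazRegion(pixels=sq))
        assert m.FC == pytest.approx(math.pi / 4, rel=0.03)
        assert m.FS == pytest.approx(1.0, abs=0.01)

    def test_two_to_one_ellipse(self):
        rr, cc = np.mgrid[0:200, 0:300]
        ell = ((rr - 100) / 50.0) ** 2 + ((cc - 150) / 100.0) ** 2 <= 1
        m = faz_shape_metrics(FazRegion(pixels=ell))
        a, b = 100.0, 50.0
        h = ((a - b) / (a + b)) ** 2
        per = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        fc_ramanujan = 4 * math.pi * (math.pi * a * b) / per**2
        assert m.FC == pytest.approx(fc_ramanujan, rel=0.03)
        assert m.FAR == pytest.approx(2.0, rel=0.02)

    def test_plus_sign_solidity(self):
        plus = np.zeros((90, 90), dtype=bool)
        plus[30:60, 0:90] = True
        plus[0:90, 30:60] = True
        m = faz_shape_metrics(FazRegion(pixels=plus))
        assert m.FS == pytest.approx(5 / 7, rel=0.03)

    def test_border_touching_flagged(self):
        half = np.zeros((60, 60), dtype=bool)
        half[0:30, 10:50] = True
        assert faz_shape_metrics(FazRegion(pixels=half)).clipped

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            faz_shape_metrics(FazRegion(pixels=np.zeros((10, 10), dtype=bool)))

    def test_fa_units_consistent(self):
        reg = FazRegion(pixels=np.pad(disk(30), 5), pixel_size_mm=0.01)
        m = faz_shape_metrics(reg)
        assert m.FA_mm2 == pytest.approx(m.FA_px * 0.01**2)
        assert m.FA_percent == pytest.approx(100.0 * m.FA_px / reg.pixels.size)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_shape_metrics_rotation_invariant(self, k):
        rng = np.random.default_rng(3)
        blob = dilation(rng.random((60, 60)) > 0.995, disk(12))
        blob = np.pad(blob, 10)
        base = faz_shape_metrics(FazRegion(pixels=blob))
        rot = faz_shape_metrics(FazRegion(pixels=np.rot90(blob, k)))
        for attr in ("FC", "FAR", "FR", "FS"):
            assert getattr(rot, attr) == pytest.approx(getattr(base, attr), rel=0.02)


class TestOrientation:
    def test_horizontal_bar(self):
        bar = np.zeros((60, 120), dtype=bool)
        bar[30, 10:110] = True
        bar = dilation(bar, disk(2))
        f = orientation_field(bar)
        med = np.degrees(np.nanmedian(f.theta[bar]))
        assert min(med, 180 - med) <= 5.0

    def test_diagonal_bar(self):
        bar = np.zeros((100, 100), dtype=bool)
        for i in range(15, 85):
            bar[i, i] = True
        bar = dilation(bar, disk(2))
        f = orientation_field(bar)
        assert np.degrees(np.nanmedian(f.theta[bar])) == pytest.approx(45.0, abs=5.0)

    def test_tree_branch_headings(self, tree_fixture):
        """Per-branch tensor orientation matches the generator's recorded
        tangent within 10 degrees (branches >= 15 px, interior samples —
        pixels within the tensor's smoothing radius of a junction pick up
        their neighbors' orientation and are excluded on both sides)."""
        _, _, mask, gt = tree_fixture
        h, w = mask.pixels.shape
        f = orientation_field(mask.pixels)
        checked = 0
        for br in gt.branches:
            if br.arc_length_px < 15 or br.chord_length_px == 0:
                continue
            pts = br.points[2:-2]
            if len(pts) < 4:
                continue
            rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
            cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
            thetas = f.theta[rr, cc]
            thetas = thetas[np.isfinite(thetas)]
            if thetas.size < 3:
                continue
            # circular means on the doubled angle (orientations are axial)
            mean_theta = 0.5 * math.atan2(
                np.mean(np.sin(2 * thetas)), np.mean(np.cos(2 * thetas))
            ) % math.pi
            seg = np.diff(pts, axis=0)
            ang = np.arctan2(seg[:, 0], seg[:, 1]) % math.pi
            truth = 0.5 * math.atan2(
                np.mean(np.sin(2 * ang)), np.mean(np.cos(2 * ang))
            ) % math.pi
            diff = abs(mean_theta - truth)
            diff = min(diff, math.pi - diff)
            assert math.degrees(diff) <= 10.0
            checked += 1
        assert checked >= 10

    def test_empty_mask_empty_field(self):
        f = orientation_field(np.zeros((20, 20), dtype=bool))
        assert not np.isfinite(f.theta).any()


class TestDirectionEllipse:
    @staticmethod
    def _field(theta):
        theta = np.asarray(theta, dtype=float)
        return OrientationField(theta=theta, coherence=np.ones_like(theta), mask=np.ones(theta.shape, bool))

    def test_isotropic_ratio_near_one(self, rng):
        e = direction_ellipse(self._field(rng.uniform(0, np.pi, 20000)))
        assert e.direction_ratio >= 0.95

    def test_area_scales_quadratically_with_counts(self, rng):
        theta = rng.uniform(0, np.pi, 20000)
        full = direction_ellipse(self._field(theta))
        half = direction_ellipse(self._field(theta[::2]))
        assert half.direction_area == pytest.approx(full.direction_area / 4.0, rel=0.05)

    def test_orthogonal_populations_fourfold_symmetric(self, rng):
        theta = np.concatenate([
            rng.normal(0.0, 0.03, 5000) % np.pi,
            rng.normal(np.pi / 2, 0.03, 5000),
        ])
        e = direction_ellipse(self._field(theta))
        assert e.direction_ratio >= 0.9

    def test_single_orientation_degenerate(self):
        e = direction_ellipse(self._field(np.full(1000, 0.5)))
        assert e.degenerate
        assert e.direction_area == 0.0 and e.direction_ratio == 0.0


class TestDensities:
    def test_full_mask_is_100(self):
        ones = np.ones((50, 50), dtype=bool)
        vad, _ = vessel_densities(ones, np.zeros_like(ones))
        assert vad == 100.0

    def test_half_mask_is_50(self):
        m = np.zeros((50, 50), dtype=bool)
        m[:25] = True
        vad, _ = vessel_densities(m, np.zeros_like(m))
        assert vad == 50.0

    def test_tree_identity(self, tree_fixture):
        params, _, mask, gt = tree_fixture
        vad, _ = vessel_densities(mask.pixels, np.zeros_like(mask.pixels))
        assert vad == pytest.approx(100.0 * gt.vessel_pixel_count / params.image_size**2)

    def test_empty_region_rejected(self):
        m = np.ones((10, 10), dtype=bool)
        with pytest.raises(ValueError):
            vessel_densities(m, m, np.zeros_like(m))

    def test_vad_at_least_vld(self, tree_fixture):
        _, _, mask, _ = tree_fixture
        g = analyze_mask(mask.pixels)
        vad, vld = vessel_densities(mask.pixels, g.skeleton)
        assert vad >= vld


class TestFractalDimension:
    def test_line(self):
        line = np.zeros((256, 256), dtype=bool)
        line[128, :] = True
        assert fractal_dimension(line) == pytest.approx(1.0, abs=0.05)

    def test_filled_square(self):
        assert fractal_dimension(np.ones((256, 256), dtype=bool)) == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_carpet(self):
        fd = fractal_dimension(_sierpinski(5), box_sizes=(3, 9, 27, 81, 243))
        assert fd == pytest.approx(math.log(8) / math.log(3), abs=0.05)

    def test_monotone_under_superset(self, rng):
        base = rng.random((128, 128)) < 0.05
        grown = dilation(base, disk(2))
        assert fractal_dimension(grown) >= fractal_dimension(base)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.ones((8, 8), dtype=bool), box_sizes=(16, 32, 64))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((64, 64), dtype=bool))


class TestMetricVector:
    def test_composition_matches_components(self, tree_fixture):
        params, image, mask, gt = tree_fixture
        from octamorph.segmentation import segment_faz

        faz = segment_faz(mask)
        vec = compute_metric_vector(mask, faz=faz)
        shape = faz_shape_metrics(faz)
        assert vec["FC"] == pytest.approx(shape.FC)
        assert vec["FS"] == pytest.approx(shape.FS)
        g = analyze_mask(mask.pixels)
        vad, vld = vessel_densities(mask.pixels, g.skeleton)
        assert vec["VAD"] == pytest.approx(vad)
        assert vec["VLD"] == pytest.approx(vld)
        assert vec["B_num"] == g.b_num

    def test_empty_mask_behavior(self):
        vec = compute_metric_vector(np.zeros((64, 64), dtype=bool), faz=None)
        assert vec["VAD"] == 0.0 and vec["VLD"] == 0.0 and vec["B_num"] == 0.0
        assert math.isnan(vec["FD"]) and math.isnan(vec["FA"])

    def test_invariants_on_fixture_suite(self, tree_suite):
        from octamorph.segmentation import segment_faz

        for params, image, mask, gt in tree_suite:
            faz = segment_faz(mask)
            vec = compute_metric_vector(mask, faz=faz)
            assert 0 < vec["FC"] <= 1.05
            assert vec["FAR"] >= 1.0
            assert vec["FR"] <= 1.05
            assert 0 < vec["FS"] <= 1.0
            assert 0 < vec["direction_ratio"] <= 1.0
            assert vec["tortuosity"] >= 1.0
            assert vec["VAD"] >= vec["VLD"] > 0
            assert 0.0 <= vec["FD"] <= 2.0
            assert vec["B_num"] == gt.bifurcation_count
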