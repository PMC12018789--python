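"""Size features vs independent geometric oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from pollenflow import (
    SyntheticObjectSpec,
    bounding_rect,
    circularity,
    compute_area,
    elongatedness,
    equivalent_diameter,
    extract_features,
    geodesic_length,
    major_axis,
    render_bead,
    render_object,
    thickness_max,
)
from pollenflow.errors import EmptyMaskError, FeatureError
from pollenflow.masking import Mask

from conftest import (
    disk_mask,
    ellipse_mask,
    horseshoe_mask,
    random_blob_mask,
    rect_mask,
)


def max_feret_px(mask):
    """Brute-force maximum caliper distance over hull vertex pairs (+1 px)."""
    coords = np.argwhere(mask.bits).astype(float)
    hull = coords[ConvexHull(coords).vertices]
    d = np.sqrt(((hull[:, None] - hull[None]) ** 2).sum(-1)).max()
    return d + 1.0


def oracle_geodesic_px(mask):
    """Independent geodesic diameter: shapely polygon visibility graph over
    all boundary pixel centres + networkx shortest paths (+1 px)."""
    import networkx as nx
    from shapely.geometry import LineString, Point, box
    from shapely.ops import unary_union

    bits = mask.bits
    poly = unary_union([
        box(j - 0.5, i - 0.5, j + 0.5, i + 0.5)
        for i, j in np.argwhere(bits)
    ]).buffer(1e-9)
    boundary = bits & ~ndi.binary_erosion(bits, structure=np.ones((3, 3), bool))
    pts = np.argwhere(boundary).astype(float)
    g = nx.Graph()
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            seg = LineString([(pts[a][1], pts[a][0]), (pts[b][1], pts[b][0])])
            if poly.covers(seg):
                g.add_edge(a, b, weight=float(np.hypot(*(pts[a] - pts[b]))))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    diam = max(max(d.values()) for d in lengths.values())
    return diam + 1.0


class TestAreaAndDiameter:
    def test_single_pixel_area(self):
        m = Mask(bits=np.eye(3, dtype=bool)[:1], kind="object")
        m.bits = np.zeros((5, 5), dtype=bool)
        m.bits[2, 2] = True
        assert compute_area(m, 0.5) == 0.25

    def test_disk_area_within_2pct(self):
        m = disk_mask(20.0)
        assert compute_area(m, 0.5) == pytest.approx(np.pi * 100, rel=0.02)

    def test_pixel_size_scaling(self):
        m = disk_mask(12.0)
        assert compute_area(m, 1.0) == 4 * compute_area(m, 0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            compute_area(Mask(bits=np.zeros((4, 4), bool), kind="object"), 0.5)

    def test_equivalent_diameter_closed_form(self):
        assert equivalent_diameter(math.pi) == pytest.approx(2.0)
        assert equivalent_diameter(100.0) == pytest.approx(11.2838, abs=1e-4)
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)

    def test_disk_equivalent_diameter_recovers_truth(self):
        m = disk_mask(20.0)
        d = equivalent_diameter(compute_area(m, 0.5))
        assert d == pytest.approx(20.0, abs=0.2)  # 2 * 20 px * 0.5 um


class TestBoundingRect:
    def test_axis_aligned_rectangle_exact(self):
        h, w = bounding_rect(rect_mask(20, 10), 0.5)
        assert (h, w) == (10.0, 5.0)

    def test_rotated_rectangle_within_one_pixel(self):
        # 20 x 10 px rectangle rotated 45 degrees
        yy, xx = np.mgrid[:40, :40]
        u = (xx - 20 + yy - 20) / math.sqrt(2)
        v = (xx - 20 - yy + 20) / math.sqrt(2)
        bits = (np.abs(u) <= 10) & (np.abs(v) <= 5)
        h, w = bounding_rect(Mask(bits=bits, kind="object"), 0.5)
        assert h == pytest.approx(10.0, abs=0.5)
        assert w == pytest.approx(5.0, abs=0.5)

    def test_disk_square_box(self):
        h, w = bounding_rect(disk_mask(20.0), 0.5)
        assert h == pytest.approx(20.0, abs=0.5)
        assert w == pytest.approx(20.0, abs=0.5)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_shapely_min_rotated_rect(self, seed):
        from shapely.geometry import MultiPoint

        mask = random_blob_mask(seed)
        coords = np.argwhere(mask.bits).astype(float)
        rect = MultiPoint([tuple(c) for c in coords]).minimum_rotated_rectangle
        xs, ys = rect.exterior.coords.xy
        pts = np.c_[xs, ys][:4]
        s1 = np.hypot(*(pts[1] - pts[0])) + 1
        s2 = np.hypot(*(pts[2] - pts[1])) + 1
        h, w = bounding_rect(mask, 1.0)
        assert h == pytest.approx(max(s1, s2), abs=1.0)
        assert w == pytest.approx(min(s1, s2), abs=1.0)

    def test_single_pixel(self):
        bits = np.zeros((8, 8), bool)
        bits[3, 3] = True
        assert bounding_rect(Mask(bits=bits, kind="object"), 0.5) == (0.5, 0.5)


class TestMajorAxis:
    def test_disk_within_3pct(self):
        assert major_axis(disk_mask(20.0), 0.5) == pytest.approx(20.0, rel=0.03)

    def test_ellipse_60x20_um(self):
        m = ellipse_mask(60.0, 20.0)  # semi-axes in px at 0.5 um -> 60x20 um
        assert major_axis(m, 0.5) == pytest.approx(60.0, rel=0.03)

    def test_square_closed_form(self):
        # moment ellipse of a square of side s has major axis s * sqrt(4/3)
        m = rect_mask(21, 21)
        assert major_axis(m, 1.0) == pytest.approx(21 * math.sqrt(4 / 3), rel=0.01)

    def test_collinear_mask_falls_back_to_length(self):
        bits = np.zeros((8, 40), bool)
        bits[4, 2:32] = True
        m = Mask(bits=bits, kind="object")
        assert major_axis(m, 0.5) == pytest.approx(geodesic_length(m, 0.5))


class TestGeodesicLength:
    def test_straight_segment_exact(self):
        bits = np.zeros((8, 60), bool)
        bits[4, 5:55] = True  # 50 px segment
        assert geodesic_length(Mask(bits=bits, kind="object"), 0.5) == 25.0

    @pytest.mark.parametrize("mask_fn,args", [
        (disk_mask, (20.0,)),
        (ellipse_mask, (25.0, 10.0)),
        (rect_mask, (30, 12)),
    ])
    def test_convex_equals_max_feret(self, mask_fn, args):
        mask = mask_fn(*args)
        assert geodesic_length(mask, 1.0) == pytest.approx(
            max_feret_px(mask), rel=0.02)

    def test_horseshoe_exceeds_feret_and_matches_oracle(self):
        mask = horseshoe_mask(r_in=9.0, r_out=15.0)
        got = geodesic_length(mask, 1.0)
        assert got > max_feret_px(mask)
        assert got == pytest.approx(oracle_geodesic_px(mask), rel=0.02)

    def test_disconnected_mask_rejected(self):
        bits = np.zeros((10, 10), bool)
        bits[2, 2] = bits[7, 7] = True
        bits[2, 3] = bits[7, 6] = True
        with pytest.raises(EmptyMaskError):
            geodesic_length(Mask(bits=bits, kind="object"), 0.5)


class TestThicknessMax:
    def test_disk_within_one_pixel(self):
        assert thickness_max(disk_mask(20.0), 0.5) == pytest.approx(20.0, abs=0.5)

    def test_rectangle_shorter_side(self):
        assert thickness_max(rect_mask(20, 10), 0.5) == pytest.approx(5.0, abs=0.5)

    def test_saccate_union_max_over_lobes(self):
        spec = SyntheticObjectSpec(shape_class="saccate", size_um=68.0,
                                   psf_sigma_um=0.0, noise_sd=0.0)
        img, _ = render_object(spec, 0.5, seed=0)
        bits = img.pixels < 0.55
        corpus_d = 68.0 / 1.7  # corpus is the widest lobe
        assert thickness_max(Mask(bits=bits, kind="object"), 0.5) == pytest.approx(
            corpus_d, abs=1.0)


class TestCircularityAndElongatedness:
    def test_disk_at_or_near_cap(self):
        assert circularity(disk_mask(24.0)) > 30

    def test_shape_ordering_disk_ellipse_doublet(self):
        disk = circularity(disk_mask(20.0))
        ell = circularity(ellipse_mask(24.0, 12.0))
        yy, xx = np.mgrid[:64, :96]
        doublet = (np.hypot(yy - 32, xx - 32) <= 16) | (np.hypot(yy - 32, xx - 61) <= 16)
        dbl = circularity(Mask(bits=doublet, kind="object"))
        assert disk > ell > dbl

    def test_scale_invariance(self):
        small = circularity(ellipse_mask(16.0, 10.0))
        large = circularity(ellipse_mask(32.0, 20.0))
        assert large == pytest.approx(small, rel=0.15)

    def test_tiny_mask_flagged(self):
        bits = np.zeros((8, 8), bool)
        bits[3:5, 3:5] = True
        with pytest.raises(FeatureError):
            circularity(Mask(bits=bits, kind="object"))

    def test_elongatedness_square_and_rect(self):
        assert elongatedness(rect_mask(15, 15)) == pytest.approx(1.0)
        assert elongatedness(rect_mask(21, 11)) == pytest.approx(
            (21.0) / (11.0), rel=0.01)

    def test_oblate_views_separate(self):
        vals = {}
        for cls in ("oblate_polar", "oblate_equatorial"):
            spec = SyntheticObjectSpec(shape_class=cls, size_um=34.0,
                                       aspect=1.6, psf_sigma_um=0.5,
                                       noise_sd=0.01)
            img, _ = render_object(spec, 0.5, seed=4)
            vals[cls] = extract_features(img).elongatedness
        assert vals["oblate_polar"] == pytest.approx(1.0, abs=0.1)
        assert vals["oblate_equatorial"] == pytest.approx(1.6, abs=0.15)


class TestInvariantsOnBlobs:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_feature_chain_and_dilation_monotonicity(self, seed):
        """thickness <= width <= height <= length + 1 px, and every size
        feature is non-decreasing under dilation."""
        mask = random_blob_mask(seed)

        def all_features(m):
            h, w = bounding_rect(m, 1.0)
            return {
                "area": compute_area(m, 1.0),
                "height": h,
                "width": w,
                "major": major_axis(m, 1.0),
                "length": geodesic_length(m, 1.0),
                "thick": thickness_max(m, 1.0),
            }

        f = all_features(mask)
        assert f["thick"] <= f["width"] + 2.0
        assert f["width"] <= f["height"]
        assert f["height"] <= f["length"] + 1.0
        dilated = Mask(bits=ndi.binary_dilation(
            np.pad(mask.bits, 3), structure=np.ones((3, 3), bool)), kind="object")
        g = all_features(dilated)
        for key in f:
            assert g[key] >= f[key] - 1e-9

    @pytest.mark.parametrize("seed", [2, 5])
    def test_linear_features_scale_with_size(self, seed):
        mask = random_blob_mask(seed)
        big = Mask(bits=np.kron(mask.bits, np.ones((2, 2), bool)), kind="object")
        for feat in (geodesic_length, thickness_max):
            assert feat(big, 1.0) == pytest.approx(2 * feat(mask, 1.0), abs=2.5)
        hb, wb = bounding_rect(big, 1.0)
        hs, ws = bounding_rect(mask, 1.0)
        assert hb == pytest.approx(2 * hs, abs=2.5)
        assert wb == pytest.approx(2 * ws, abs=2.5)


class TestExtractFeatures:
    def test_bead_length_within_one_pixel(self):
        img, _ = render_bead(19.98, 0.5, psf_sigma_um=0.5, noise_sd=0.01, seed=3)
        rec = extract_features(img, object_id="bead")
        assert rec.status == "ok"
        assert abs(rec.length_um - 19.98) <= 0.5

    def test_cropped_object_flagged(self):
        spec = SyntheticObjectSpec(shape_class="cropped", size_um=32.0)
        img, _ = render_object(spec, 0.5, seed=1)
        assert extract_features(img).border_touch

    def test_all_size_features_of_disk_agree_with_truth(self):
        img, _ = render_bead(30.0, 0.5, psf_sigma_um=0.5, noise_sd=0.01, seed=0)
        rec = extract_features(img)
        for value in (rec.diameter_um, rec.height_um, rec.width_um,
                      rec.major_axis_um, rec.length_um, rec.thickness_max_um):
            assert value == pytest.approx(30.0, rel=0.03)

    def test_blank_image_gets_error_status(self):
        from pollenflow.masking import ObjectImage

        rng = np.random.default_rng(0)
        img = ObjectImage(pixels=0.8 + rng.normal(0, 0.01, (32, 32)).clip(-0.7, 0.2),
                          pixel_size_um=0.5)
        rec = extract_features(img, object_id="blank")
        assert rec.status == "empty_object"
        assert math.isnan(rec.length_um)

    def test_eq1_identity_exact(self):
        img, _ = render_bead(22.0, 0.5, seed=9)
        rec = extract_features(img)
        assert rec.diameter_um == 2.0 * math.sqrt(rec.area_um2 / math.pi)
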