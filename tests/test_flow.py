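"""Dense-flow estimation, radial filtering and quadrant pooling."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from tunnelvision import (
    estimate_dense_flow,
    quadrant_masks,
    quadrant_mean,
    render_fisheye_sequence,
    scene_flow_summary,
    temporal_mean_magnitude,
    translational_filter,
)
from tunnelvision.synthetic.scene import analytic_flow_map


def textured_image(seed=0, size=100):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=(size, size)), 2.0)
    return (img - img.min()) / np.ptp(img)


class TestEstimateDenseFlow:
    def test_static_sequence_near_zero(self):
        img = textured_image()
        fields = estimate_dense_flow(np.stack([img, img]))
        assert np.abs(fields).max() < 0.02

    def test_global_shift_recovered(self):
        img = textured_image(1, 120)
        shifted = np.roll(img, 1, axis=1)  # 1 px along columns
        fields = estimate_dense_flow(np.stack([img, shifted]))
        inner = fields[0, 20:-20, 20:-20]
        assert 0.9 <= np.median(inner[..., 0]) <= 1.1
        assert np.median(np.abs(inner[..., 1])) < 0.1

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_dense_flow(textured_image()[None])

    def test_forward_translation_flow_is_radial(self, floor_scene):
        seq = render_fisheye_sequence(floor_scene)
        fields = estimate_dense_flow(seq)
        h, w = seq.shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        rx, ry = cols - cx, rows - cy
        rho = np.hypot(rx, ry)
        mag = np.hypot(fields[0, ..., 0], fields[0, ..., 1])
        sel = (rho > 15) & (rho < 50) & (ry > 0) & (mag > 0.3)  # textured ventral field
        with np.errstate(invalid="ignore"):
            cosang = (fields[0, ..., 0] * rx + fields[0, ..., 1] * ry) / (mag * rho)
        dev = np.degrees(np.arccos(np.clip(cosang[sel], -1, 1)))
        assert np.median(dev) < 15.0


class TestTranslationalFilter:
    def test_radial_vector_kept_tangential_zeroed(self):
        field = np.zeros((50, 50, 2))
        field[40, 25] = (0.0, 2.0)  # below centre, pointing down = outward
        field[25, 40] = (0.0, 2.0)  # right of centre, pointing down = tangential
        out = translational_filter(field)
        assert np.allclose(out[40, 25], (0.0, 2.0))
        assert np.allclose(out[25, 40], 0.0)

    def test_inward_vector_zeroed(self):
        field = np.zeros((50, 50, 2))
        field[40, 25] = (0.0, -2.0)  # pointing back to the FOE
        assert np.allclose(translational_filter(field)[40, 25], 0.0)

    def test_foe_neighbourhood_zeroed(self):
        field = np.ones((50, 50, 2))
        out = translational_filter(field)
        assert np.allclose(out[24:26, 24:26], 0.0)

    def test_isotropic_directions_keep_one_sixth(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, (200, 200))
        field = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        out = translational_filter(field, angle_tol_deg=30.0)
        h, w = 200, 200
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        rho = np.hypot(cols - 99.5, rows - 99.5)
        sel = rho > 5
        kept = (np.hypot(out[..., 0], out[..., 1]) > 0)[sel].mean()
        assert kept == pytest.approx(1.0 / 6.0, abs=0.01)

    def test_foe_outside_image_rejected(self):
        with pytest.raises(ValueError):
            translational_filter(np.zeros((20, 20, 2)), foe=(30.0, 5.0))


class TestTemporalMean:
    def test_all_zero_fields_zero_map(self):
        fmap = temporal_mean_magnitude(np.zeros((4, 30, 30, 2)))
        assert np.all(fmap.magnitude == 0.0)

    def test_constant_magnitude_preserved_and_half_duty_halved(self):
        fields = np.zeros((4, 30, 30, 2))
        fields[:, 15, 20, 0] = 3.0  # kept in all pairs
        fields[:2, 20, 15, 1] = 3.0  # kept in half the pairs
        fmap = temporal_mean_magnitude(fields)
        assert fmap.magnitude[15, 20] == pytest.approx(3.0)
        assert fmap.magnitude[20, 15] == pytest.approx(1.5)

    def test_kept_only_mean_ignores_rejected_pairs(self):
        fields = np.zeros((4, 30, 30, 2))
        fields[:2, 20, 15, 1] = 3.0
        fmap = temporal_mean_magnitude(fields, include_rejected_as_zero=False)
        assert fmap.magnitude[20, 15] == pytest.approx(3.0)


class TestQuadrants:
    def test_cardinal_pixels_assigned_to_expected_sectors(self):
        masks = quadrant_masks(101, 101)
        assert masks["dorsal"][10, 50]  # straight above centre
        assert masks["ventral"][90, 50]
        assert masks["left"][50, 10]
        assert masks["right"][50, 90]

    def test_sectors_partition_circle_with_equal_areas(self):
        masks = quadrant_masks(200, 200)
        union = np.zeros((200, 200), int)
        for m in masks.values():
            union += m.astype(int)
        assert union.max() == 1  # disjoint
        circle_area = union.sum()
        for m in masks.values():
            assert abs(m.sum() - circle_area / 4) < 0.01 * circle_area

    def test_uniform_map_gives_equal_means(self):
        masks = quadrant_masks(60, 60)
        qs = quadrant_mean(np.full((60, 60), 2.5), masks)
        assert all(v == pytest.approx(2.5) for v in qs.means.values())

    def test_ventral_only_map_leaves_dorsal_zero(self):
        masks = quadrant_masks(60, 60)
        arr = np.where(masks["ventral"], 1.0, 0.0)
        qs = quadrant_mean(arr, masks)
        assert qs.means["dorsal"] == 0.0
        assert qs.means["ventral"] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        masks = quadrant_masks(60, 60)
        masks["dorsal"] = np.zeros((60, 60), bool)
        with pytest.raises(ValueError, match="empty quadrant"):
            quadrant_mean(np.ones((60, 60)), masks)

    def test_lateral_combination_is_area_weighted(self):
        masks = quadrant_masks(60, 60)
        arr = np.where(masks["left"], 2.0, 0.0) + np.where(masks["right"], 4.0, 0.0)
        qs = quadrant_mean(arr, masks, combine_lateral=True)
        nl, nr = qs.n_pixels["left"], qs.n_pixels["right"]
        assert qs.lateral_combined == pytest.approx((2.0 * nl + 4.0 * nr) / (nl + nr))


class TestSceneSummary:
    def test_floor_scene_ventral_dominates_and_matches_oracle(self, floor_scene):
        seq = render_fisheye_sequence(floor_scene)
        fmap, qs = scene_flow_summary(seq)
        assert qs.means["ventral"] > qs.means["dorsal"]
        assert qs.means["ventral"] > 2 * max(qs.means["left"], qs.means["right"])
        # analytic oracle through the identical filter and masks
        amap = analytic_flow_map(floor_scene)
        afm = temporal_mean_magnitude(translational_filter(amap[None]))
        h, w = seq.shape
        masks = quadrant_masks(w, h, radius=min(w, h) / 2.0 - 8.0)
        aq = quadrant_mean(afm, masks)
        assert qs.means["ventral"] == pytest.approx(aq.means["ventral"], rel=0.15)
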