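"""Image-to-profile quantification: decomposition, intensity measurement,
editing and standardization."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from nemagrn import quantification as q
from nemagrn import synthetic_data as sd
from nemagrn.morphology import annulus_morphology


class TestDecomposeCellLayer:
    def test_annulus_segment_geometry(self, annulus):
        """100 segments of an annulus between r=40 and r=60: inner edges
        approximate arcs of length 2 pi 40 / 100."""
        decomp = q.decompose_cell_layer(annulus, n_segments=100)
        assert decomp.n_segments == 100
        inner_edges = np.linalg.norm(decomp.quads[:, 2] - decomp.quads[:, 3], axis=1)
        expected = 2 * np.pi * 40 / 100
        np.testing.assert_allclose(inner_edges, expected, rtol=5e-3)

    def test_segment_count_scales_with_width(self, annulus):
        layer = q.decompose_cell_layer(annulus, segment_width=10.0)
        half = q.decompose_cell_layer(annulus, segment_width=20.0)
        assert abs(layer.n_segments - 2 * half.n_segments) <= 2

    def test_positions_monotone(self, annulus):
        decomp = q.decompose_cell_layer(annulus, n_segments=50)
        assert np.all(np.diff(decomp.positions) > 0)

    def test_excessive_width_rejected(self, annulus):
        with pytest.raises(q.QuantificationError):
            q.decompose_cell_layer(annulus, segment_width=1e6)

    def test_degenerate_layer_rejected(self, annulus):
        import dataclasses
        flat = dataclasses.replace  # noqa: F841 (kept simple below)
        from nemagrn.morphology import Morphology
        m = Morphology(annulus.outer_loop, annulus.outer_loop.copy(),
                       annulus.oral_anchor, annulus.stage_hours)
        with pytest.raises(q.QuantificationError):
            q.decompose_cell_layer(m, n_segments=50)


class TestMeasureIntensity:
    def test_constant_image(self, annulus):
        decomp = q.decompose_cell_layer(annulus, n_segments=60)
        image = np.full((200, 200), 0.37)
        raw = q.measure_intensity(image, decomp, "gray")
        valid = np.isfinite(raw.intensities)
        assert valid.all()
        np.testing.assert_allclose(raw.intensities, 0.37)

    def test_half_plane_area_fractions(self, annulus):
        """A 0|1 half-plane image split through the annulus center: segment
        means match the polygon-clipped covered-area fractions."""
        decomp = q.decompose_cell_layer(annulus, n_segments=40)
        image = np.zeros((200, 200))
        image[:, 100:] = 1.0  # x >= 100 is bright
        raw = q.measure_intensity(image, decomp, "gray")
        bright = box(99.5, -1, 300, 300)  # pixel centers at x >= 100
        for i, quad in enumerate(decomp.quads):
            poly = Polygon(quad)
            frac = poly.intersection(bright).area / poly.area
            if np.isfinite(raw.intensities[i]):
                assert abs(raw.intensities[i] - frac) < 0.08

    def test_empty_segment_flagged_missing(self):
        tiny = annulus_morphology(center=(100, 100), r_inner=30, r_outer=30.4,
                                  n_points=64)
        decomp = q.decompose_cell_layer(tiny, n_segments=500)
        raw = q.measure_intensity(np.ones((200, 200)), decomp, "gray")
        assert np.isnan(raw.intensities).any()

    def test_unknown_channel_rejected(self, annulus):
        decomp = q.decompose_cell_layer(annulus, n_segments=20)
        with pytest.raises(q.QuantificationError):
            q.measure_intensity(np.ones((200, 200)), decomp, "alpha")


class TestEditProfile:
    def test_constant_profile_becomes_zero(self):
        edited = q.edit_profile(np.full(50, 0.4), q.EditRules(background_pct=5.0))
        np.testing.assert_allclose(edited, 0.0)

    def test_mask_removes_spike_keeps_neighbors(self):
        values = np.linspace(1, 2, 20)
        spiked = values.copy()
        spiked[10] = 50.0  # annotation artifact
        edited = q.edit_profile(spiked, q.EditRules(background_pct=None,
                                                    masks=((10, 10),)))
        np.testing.assert_allclose(edited[10], (values[9] + values[11]) / 2)
        np.testing.assert_allclose(np.delete(edited, 10), np.delete(spiked, 10))

    def test_disabled_rules_identity(self, rng):
        values = rng.uniform(0, 1, 30)
        np.testing.assert_array_equal(
            q.edit_profile(values, q.EditRules(background_pct=None)), values)

    def test_full_mask_rejected(self):
        with pytest.raises(q.QuantificationError):
            q.edit_profile(np.ones(10), q.EditRules(masks=((0, 9),)))


class TestStandardize:
    def test_unit_maximum(self, rng):
        for _ in range(5):
            values = rng.uniform(0, 3, 73)
            prof = q.standardize(values, oral_segment=10)
            assert len(prof.values) == 100
            assert prof.values.max() == pytest.approx(1.0)
            assert prof.values.min() >= 0.0

    def test_zero_guard(self):
        prof = q.standardize(np.zeros(40), oral_segment=0)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_idempotent_on_standard_input(self):
        template = sd.make_template("endodermal").values
        prof = q.standardize(template, oral_segment=49)
        np.testing.assert_allclose(prof.values, template, atol=1e-9)

    def test_anchor_rotates_to_position_50(self):
        # a delta at the oral anchor must land at output index 49 (segment 50)
        values = np.zeros(100)
        values[20] = 1.0
        prof = q.standardize(values, oral_segment=20)
        assert int(np.argmax(prof.values)) == 49

    def test_flip_mirrors_profile(self):
        values = np.zeros(100)
        values[30] = 1.0
        plain = q.standardize(values, oral_segment=49)
        flipped = q.standardize(values, oral_segment=49, flip=True)
        assert int(np.argmax(plain.values)) + int(np.argmax(flipped.values)) == 98

    def test_too_few_segments_rejected(self):
        with pytest.raises(q.QuantificationError):
            q.standardize(np.array([np.nan, np.nan, 1.0]), 0)


class TestImageRoundTrip:
    def test_endodermal_peak_recovered(self, annulus):
        """Render a known staining, quantify it back: the profile's argmax
        must land within 3 segments of the template's argmax."""
        template = sd.make_template("endodermal")
        spec = sd.SyntheticImageSpec(morphology=annulus,
                                     layer_profile=template.values)
        image, morph = sd.render_embryo_image(spec)
        prof = q.quantify_image(image, morph, channel="R",
                                rules=q.EditRules(background_pct=None))
        assert abs(int(np.argmax(prof.values)) - int(np.argmax(template.values))) <= 3

    def test_brightness_scaling_invariance(self, annulus):
        template = sd.make_template("oral")
        spec = sd.SyntheticImageSpec(morphology=annulus,
                                     layer_profile=template.values)
        image, morph = sd.render_embryo_image(spec)
        rules = q.EditRules(background_pct=None)
        p1 = q.quantify_image(image, morph, channel="R", rules=rules)
        p2 = q.quantify_image(image * 0.4, morph, channel="R", rules=rules)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_rotation_invariance(self, annulus):
        """Rotating image and morphology together by 90 degrees leaves the
        standardized profile unchanged within interpolation tolerance."""
        from nemagrn.morphology import Morphology
        template = sd.make_template("endodermal")
        spec = sd.SyntheticImageSpec(morphology=annulus,
                                     layer_profile=template.values)
        image, morph = sd.render_embryo_image(spec)
        h = image.shape[0]
        rot_image = np.rot90(image, k=1)  # (x, y) -> (y, h-1-x)
        def rot(loop):
            return np.column_stack([loop[:, 1], h - 1 - loop[:, 0]])
        rot_morph = Morphology(rot(morph.outer_loop), rot(morph.inner_loop),
                               morph.oral_anchor, morph.stage_hours)
        rules = q.EditRules(background_pct=None)
        p1 = q.quantify_image(image, morph, channel="R", rules=rules)
        p2 = q.quantify_image(rot_image, rot_morph, channel="R", rules=rules)
        np.testing.assert_allclose(p1.values, p2.values, atol=0.08)
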