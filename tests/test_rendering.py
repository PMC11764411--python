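"""Composite algebra: brightfield multiplicativity, fluorescence additivity,
DAB-mimic and H&E reconstruction, grayscale and saturation controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import spectraplex as spx
from spectraplex.errors import ConfigurationError
from spectraplex.rendering import CompositeSpec


def _spec(mode, colors):
    return CompositeSpec(
        included_stains=tuple(colors), mode=mode, colors=dict(colors)
    )


_COLORS = {"a": (0.3, 0.6, 0.9), "b": (0.8, 0.2, 0.5)}

maps_strategy = hnp.arrays(
    dtype=float,
    shape=(6, 6),
    elements=st.floats(0.0, 2.0, allow_nan=False),
)


class TestBrightfield:
    def test_zero_abundance_is_pure_white(self):
        maps = {"a": np.zeros((5, 5)), "b": np.zeros((5, 5))}
        img = spx.brightfield_composite(maps, _spec("brightfield", _COLORS))
        assert np.all(img == 1.0)

    def test_unit_abundance_gives_the_stain_color(self):
        maps = {"a": np.ones((3, 3))}
        img = spx.brightfield_composite(
            maps, _spec("brightfield", {"a": _COLORS["a"]})
        )
        np.testing.assert_allclose(img[1, 1], _COLORS["a"], atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(m1=maps_strategy, m2=maps_strategy)
    def test_multiplicative_over_abundance_partitions(self, m1, m2):
        spec = _spec("brightfield", {"a": _COLORS["a"]})
        combined = spx.brightfield_composite({"a": m1 + m2}, spec)
        product = spx.brightfield_composite({"a": m1}, spec) * spx.brightfield_composite(
            {"a": m2}, spec
        )
        np.testing.assert_allclose(combined, product, atol=1e-6)

    def test_monotone_darkening(self):
        spec = _spec("brightfield", {"a": _COLORS["a"]})
        imgs = [
            spx.brightfield_composite({"a": np.full((2, 2), lvl)}, spec)
            for lvl in (0.0, 0.5, 1.0, 2.0)
        ]
        for lo, hi in zip(imgs[1:], imgs[:-1]):
            assert np.all(lo <= hi + 1e-12)

    def test_missing_map_rejected(self):
        with pytest.raises(ConfigurationError):
            spx.brightfield_composite({"a": np.ones((2, 2))}, _spec("brightfield", _COLORS))


class TestDabMimic:
    def test_biomarker_pixel_is_brown(self):
        img = spx.dab_mimic(np.ones((2, 2)), np.zeros((2, 2)))
        r, g, b = img[0, 0]
        assert r > g > b

    def test_hematoxylin_pixel_is_blue(self):
        img = spx.dab_mimic(np.zeros((2, 2)), np.ones((2, 2)))
        r, g, b = img[0, 0]
        assert b > r

    def test_unstained_pixel_is_white(self):
        img = spx.dab_mimic(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.all(img == 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            spx.dab_mimic(np.zeros((2, 2)), np.zeros((3, 3)))


class TestHEReconstruction:
    def _colors(self, cfg):
        lib = {s.name: s for s in cfg.stains}
        return (
            lib["hematoxylin"].display_color_rgb,
            lib["eosin"].display_color_rgb,
        )

    def test_matches_simulated_white_light_capture(self, prostate_cfg,
                                                   prostate_truth_matrix):
        # H&E-only slide: reconstruction from unmixed maps vs the white-light
        # transmittance, display-space agreement
        slide = spx.generate_tissue(prostate_cfg, [], 128, 128, seed=3)
        caps = spx.render_assay(slide, prostate_cfg)
        white = next(c for c in caps if c.channel_name == "white")
        res = spx.unmix_stack(
            spx.od_stack_from_captures(caps, prostate_cfg), prostate_truth_matrix
        )
        h_color, e_color = self._colors(prostate_cfg)
        rec = spx.he_reconstruction(
            res.map("hematoxylin"), res.map("eosin"), h_color, e_color
        )
        err = np.abs(rec - white.transmittance()).mean(axis=(0, 1))
        assert np.all(err < 0.1)

    def test_zero_gains_give_white_image(self, prostate_cfg):
        h_color, e_color = self._colors(prostate_cfg)
        img = spx.he_reconstruction(
            np.ones((4, 4)), np.ones((4, 4)), h_color, e_color, gains=(0.0, 0.0)
        )
        assert np.all(img == 1.0)

    def test_eosin_only_gain_hides_hematoxylin(self, prostate_cfg):
        h_color, e_color = self._colors(prostate_cfg)
        img = spx.he_reconstruction(
            np.ones((4, 4)), np.ones((4, 4)), h_color, e_color, gains=(0.0, 1.0)
        )
        np.testing.assert_allclose(img[0, 0], e_color, atol=1e-12)

    def test_negative_gain_rejected(self, prostate_cfg):
        h_color, e_color = self._colors(prostate_cfg)
        with pytest.raises(ConfigurationError):
            spx.he_reconstruction(
                np.ones((2, 2)), np.ones((2, 2)), h_color, e_color, gains=(-1.0, 1.0)
            )


class TestFluorescenceLike:
    def test_zero_abundance_is_black(self):
        maps = {"a": np.zeros((4, 4)), "b": np.zeros((4, 4))}
        img = spx.fluorescence_composite(maps, _spec("fluorescence_like", _COLORS))
        assert np.all(img == 0.0)

    def test_unit_abundance_gives_the_fluor_color(self):
        img = spx.fluorescence_composite(
            {"a": np.ones((2, 2))}, _spec("fluorescence_like", {"a": _COLORS["a"]})
        )
        np.testing.assert_allclose(img[0, 0], _COLORS["a"], atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(m1=maps_strategy, m2=maps_strategy)
    def test_additive_for_disjoint_stains(self, m1, m2):
        # pre-clip additivity: check at abundances that keep the sum in range
        m1, m2 = m1 / 4, m2 / 4
        spec = _spec("fluorescence_like", _COLORS)
        union = spx.fluorescence_composite({"a": m1, "b": m2}, spec)
        parts = spx.fluorescence_composite(
            {"a": m1, "b": np.zeros_like(m2)}, spec
        ) + spx.fluorescence_composite({"a": np.zeros_like(m1), "b": m2}, spec)
        np.testing.assert_allclose(union, parts, atol=1e-6)

    def test_channel_permutation_equivariance(self, rng):
        m = rng.uniform(0, 0.5, (4, 4))
        spec = _spec("fluorescence_like", {"a": (0.2, 0.5, 0.8)})
        img = spx.fluorescence_composite({"a": m}, spec)
        spec_perm = _spec("fluorescence_like", {"a": (0.8, 0.2, 0.5)})
        img_perm = spx.fluorescence_composite({"a": m}, spec_perm)
        np.testing.assert_allclose(img[..., [2, 0, 1]], img_perm, atol=1e-12)

    def test_wrong_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            spx.fluorescence_composite({"a": np.ones((2, 2))}, _spec("brightfield", _COLORS))


class TestGrayscaleAndSaturation:
    def test_grayscale_view_extracts_the_plane(self, prostate_cfg, prostate_captures):
        cap = next(c for c in prostate_captures if c.channel_name == "nir880")
        mono = spx.grayscale_view(cap, "blue")
        np.testing.assert_array_equal(mono, cap.rgb[..., 2])

    def test_blank_capture_views_uniform(self, prostate_cfg, prostate_captures):
        cap = prostate_captures[0]
        mono = spx.grayscale_view(
            spx.ChannelCapture("blank", cap.blank_rgb, cap.blank_rgb), "green"
        )
        assert np.ptp(mono) == 0

    def test_gray_triple_from_plane_is_neutral(self, prostate_captures):
        cap = next(c for c in prostate_captures if c.channel_name == "nir880")
        mono = spx.grayscale_view(cap, "blue")
        rgb = np.stack([mono] * 3, axis=-1)
        hsv_sat = spx.adjust_saturation(rgb, 1.0)
        np.testing.assert_allclose(hsv_sat, rgb, atol=1e-6)

    def test_factor_one_is_identity(self, rng):
        rgb = rng.uniform(0, 1, (8, 8, 3))
        np.testing.assert_allclose(spx.adjust_saturation(rgb, 1.0), rgb, atol=1e-6)

    def test_factor_zero_gives_grayscale(self, rng):
        rgb = rng.uniform(0, 1, (8, 8, 3))
        out = spx.adjust_saturation(rgb, 0.0)
        np.testing.assert_allclose(out[..., 0], out[..., 1], atol=1e-9)
        np.testing.assert_allclose(out[..., 1], out[..., 2], atol=1e-9)

    def test_value_channel_preserved(self, rng):
        rgb = rng.uniform(0, 1, (8, 8, 3))
        out = spx.adjust_saturation(rgb, 0.6)
        np.testing.assert_allclose(out.max(axis=-1), rgb.max(axis=-1), atol=1e-9)

    def test_print_factor_maps_full_saturation_to_60_percent(self):
        from skimage.color import rgb2hsv

        pure_blue = np.zeros((2, 2, 3))
        pure_blue[..., 2] = 1.0  # saturation 1
        out = spx.adjust_saturation(pure_blue, 0.6)
        assert rgb2hsv(out)[0, 0, 1] == pytest.approx(0.6, abs=1e-9)

    @pytest.mark.parametrize("factor", [-0.1, 1.1])
    def test_out_of_range_factor_rejected(self, factor):
        with pytest.raises(ConfigurationError):
            spx.adjust_saturation(np.ones((2, 2, 3)), factor)
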