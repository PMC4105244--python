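"""Crease detection: axial filtering, path tracing, colour partition."""

import numpy as np
import pytest

import grainscan as gs
from grainscan.core import LabelMap
from grainscan.crease import find_crease_path

from conftest import match_to_truth


def _ellipse(shape, center, a, b, phi=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dr = yy - center[0]
    dc = xx - center[1]
    u = dr * np.cos(phi) + dc * np.sin(phi)
    v = -dr * np.sin(phi) + dc * np.cos(phi)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0), u, v


class TestDirectionalMeanFilter:
    def test_constant_grain_unchanged(self):
        gray = np.full((40, 80), 150.0)
        mask, _, _ = _ellipse((40, 80), (20, 40), 35, 15, np.pi / 2)
        out = gs.directional_mean_filter(gray, mask, np.pi / 2, k=9)
        np.testing.assert_allclose(out, gray)

    def test_axial_stripe_preserved(self):
        # dark stripe parallel to the (horizontal) axis survives axial
        # averaging: every window lies within the stripe
        gray = np.full((41, 81), 150.0)
        mask, _, _ = _ellipse((41, 81), (20, 40), 38, 16, np.pi / 2)
        stripe = mask & (np.abs(np.arange(41)[:, None] - 20) <= 1)
        gray[stripe] = 60.0
        out = gs.directional_mean_filter(gray, mask, np.pi / 2, k=9)
        inner = stripe & (np.abs(np.arange(81)[None, :] - 40) < 25)
        assert np.allclose(out[inner], 60.0)

    def test_perpendicular_blip_attenuated(self):
        gray = np.full((41, 81), 150.0)
        mask, _, _ = _ellipse((41, 81), (20, 40), 38, 16, np.pi / 2)
        gray[15:26, 40] = 30.0  # 1-px extent along the axis
        k = 9
        out = gs.directional_mean_filter(gray, mask, np.pi / 2, k=k)
        # impulse of depth 120 spread over k samples: residual ≈ 120/k
        assert out[20, 40] == pytest.approx(150 - 120 / k, abs=2.0)

    def test_invalid_k(self):
        with pytest.raises(gs.ValidationError):
            gs.directional_mean_filter(np.zeros((5, 5)), np.ones((5, 5), bool), 0.0, k=4)


class TestFindCreasePath:
    def _grain_with_crease(self, phi, depth=60.0, sinuous=False):
        shape = (160, 160)
        mask, u, v = _ellipse(shape, (80, 80), 45, 18, phi)
        gray = np.full(shape, 14.0)
        gray[mask] = 150.0
        if sinuous:
            wobble = 2.0 * np.sin(u / 12.0)
            stripe = mask & (np.abs(v - wobble) <= 1.5)
        else:
            stripe = mask & (np.abs(v) <= 1.5)
        gray[stripe] = 150.0 - depth
        return gray, mask, stripe

    @pytest.mark.parametrize("phi", [np.pi / 2, 0.0, 0.6, -1.1])
    def test_straight_crease_tracked(self, phi):
        gray, mask, stripe = self._grain_with_crease(phi)
        filtered = gs.directional_mean_filter(gray, mask, phi, k=9)
        res = find_crease_path(filtered, mask, phi, grain_id=1, tau=15.0)
        assert res.crease_detected
        on_stripe = stripe[res.path_rows, res.path_cols].mean()
        assert on_stripe >= 0.95

    def test_crease_free_noise_not_detected(self):
        rng = np.random.default_rng(6)
        shape = (120, 160)
        mask, _, _ = _ellipse(shape, (60, 80), 45, 18, np.pi / 2)
        gray = np.full(shape, 14.0)
        gray[mask] = 150.0
        gray = gray + rng.normal(0, 3.0, shape)
        filtered = gs.directional_mean_filter(gray, mask, np.pi / 2, k=9)
        res = find_crease_path(filtered, mask, np.pi / 2, tau=15.0)
        assert not res.crease_detected

    def test_sinuous_crease_tracked(self):
        phi = np.pi / 2
        gray, mask, stripe = self._grain_with_crease(phi, sinuous=True)
        filtered = gs.directional_mean_filter(gray, mask, phi, k=9)
        res = find_crease_path(filtered, mask, phi, tau=15.0)
        assert res.crease_detected
        assert stripe[res.path_rows, res.path_cols].mean() >= 0.90

    def test_tiny_grain_no_error(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4:6] = True
        res = find_crease_path(np.zeros((10, 10)), mask, 0.0)
        assert not res.crease_detected

    def test_crease_mask_inside_grain(self):
        gray, mask, _ = self._grain_with_crease(0.4)
        filtered = gs.directional_mean_filter(gray, mask, 0.4, k=9)
        res = find_crease_path(filtered, mask, 0.4, tau=15.0)
        assert res.crease_detected
        assert mask[res.crease_rows, res.crease_cols].all()


class TestPartitionColour:
    def _scene(self):
        spec = gs.wheat_spec(
            n_grains=8, seed=21, crease_fraction=0.5, crease_depth=60, noise_sd=3.0
        )
        image, truth = gs.render_grain_field(spec)
        cfg = gs.PipelineConfig(crease_enabled=True)
        return gs.analyse_image(image, cfg), image, truth

    def test_weighted_mean_identity_exact(self):
        result, image, _ = self._scene()
        lab = result.labels.labels
        px = image.pixels
        for res in result.creases:
            if not res.crease_detected:
                continue
            gmask = lab == res.grain_id
            cmask = np.zeros_like(gmask)
            cmask[res.crease_rows, res.crease_cols] = True
            cmask &= gmask
            nmask = gmask & ~cmask
            rec = next(r for r in result.records if r.grain_id == res.grain_id)
            whole = np.array([rec.mean_R, rec.mean_G, rec.mean_B])
            combined = (
                px[cmask].astype(np.int64).sum(axis=0)
                + px[nmask].astype(np.int64).sum(axis=0)
            ) / gmask.sum()
            np.testing.assert_array_equal(whole, combined)

    def test_partition_is_disjoint_and_complete(self):
        result, _, _ = self._scene()
        lab = result.labels.labels
        for res in result.creases:
            if not res.crease_detected:
                continue
            gmask = lab == res.grain_id
            cmask = np.zeros_like(gmask)
            cmask[res.crease_rows, res.crease_cols] = True
            assert (cmask & ~gmask).sum() == 0  # crease ⊆ grain
            nmask = gmask & ~cmask
            assert (cmask & nmask).sum() == 0
            assert (cmask | nmask).sum() == gmask.sum()

    def test_synthetic_two_tone_grain_means(self):
        """Body at one colour, crease stripe at another: GS mean is the
        area-weighted mix; the non-crease mean recovers the body colour."""
        px = np.zeros((60, 100, 3), dtype=np.uint8)
        labels = np.zeros((60, 100), dtype=np.int32)
        body = (150, 100, 60)
        stripe_col = (60, 40, 25)
        labels[10:50, 10:90] = 1
        px[10:50, 10:90] = body
        px[28:32, 10:90] = stripe_col  # 10 % of grain pixels
        image = gs.RasterImage(pixels=px, dpi=300)
        crease = gs.CreaseResult(
            grain_id=1,
            crease_detected=True,
            crease_rows=np.repeat(np.arange(28, 32), 80),
            crease_cols=np.tile(np.arange(10, 90), 4),
        )
        rec = gs.GrainRecord(grain_id=1)
        gs.partition_colour(image, LabelMap(labels), [crease], [rec])
        expected = tuple(0.9 * b + 0.1 * s for b, s in zip(body, stripe_col))
        assert (rec.mean_R, rec.mean_G, rec.mean_B) == pytest.approx(expected)

    def test_no_crease_grain_flagged(self):
        result, _, truth = self._scene()
        pairs = match_to_truth(result.records, truth)
        assert pairs
        for rec, row in pairs:
            assert rec.crease_detected == bool(row.has_crease)

    def test_gs_equals_gsncd_when_crease_free(self):
        spec = gs.wheat_spec(n_grains=8, seed=22, crease_fraction=0.0, noise_sd=3.0)
        image, _ = gs.render_grain_field(spec)
        result = gs.analyse_image(image, gs.PipelineConfig(crease_enabled=True))
        modes = gs.colour_mode_means(image, result.labels, result.creases)
        np.testing.assert_array_equal(modes["GS"], modes["GSncd"])
        assert modes["GSwc"] is None
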