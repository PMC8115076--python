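"""Stimulus generation: exact identities, balance, determinism, I/O."""

import dataclasses

import numpy as np
import pytest

from ltbseg import (CompositeSpec, LSBSpec, LTBSpec, compose, lsb_contrast_ladder,
                    ltb_pi_ladder, make_lsb, make_ltb, measure, rms_contrast)
from ltbseg.stimulus import (EXCLUSION_DISTANCE, PlacementError, snap_pi_u,
                             load_stimulus, save_stimulus)


class TestLTB:
    def test_determinism(self):
        spec = LTBSpec(n_p=32, pi_U=0.5, seed=7)
        a, b = make_ltb(spec), make_ltb(spec)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.micropattern_centers == b.micropattern_centers

    def test_pixel_range_and_background(self, ltb_default):
        img = ltb_default
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        assert np.all(img.pixels[~img.disc_mask] == 0.5)

    @pytest.mark.parametrize("A", [0.1, 0.25, 0.4])
    def test_michelson_contrast_is_twice_amplitude(self, A):
        img = make_ltb(LTBSpec(n_p=32, pi_U=0.5, A=A, seed=3))
        assert img.michelson_contrast() == pytest.approx(2 * A, abs=1e-12)

    def test_fully_unbalanced_sides_are_single_polarity(self):
        img = make_ltb(LTBSpec(n_p=32, pi_U=1.0, phase=0, seed=2))
        by_side = {1: [], -1: []}
        for x, y, pol in img.micropattern_centers:
            by_side[1 if (y - x) > 0 else -1].append(pol)
        # phase 0: the d > 0 half is the white-majority side
        assert by_side[1] == [1] * 32
        assert by_side[-1] == [-1] * 32

    def test_fully_balanced_sides_have_equal_polarity_counts(self):
        img = make_ltb(LTBSpec(n_p=32, pi_U=0.0, seed=5))
        for side in (1, -1):
            pols = [p for x, y, p in img.micropattern_centers
                    if (1 if (y - x) > 0 else -1) == side]
            assert len(pols) == 32 and sum(pols) == 0
        assert measure(img).L_R == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("orientation", ["left_oblique", "right_oblique"])
    @pytest.mark.parametrize("seed", range(5))
    def test_antidiagonal_luminance_difference_is_zero(self, orientation, seed):
        img = make_ltb(LTBSpec(n_p=32, pi_U=0.75, orientation=orientation,
                               seed=seed))
        fv = measure(img)
        off_axis = fv.L_L if orientation == "right_oblique" else fv.L_R
        assert off_axis <= 1e-12

    def test_micropatterns_never_overlap(self, ltb_default):
        pts = np.array([(x, y) for x, y, _ in ltb_default.micropattern_centers])
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= EXCLUSION_DISTANCE

    def test_quadrant_counts_equal_per_polarity(self):
        img = make_ltb(LTBSpec(n_p=32, pi_U=0.5, seed=9))
        counts = {}
        for x, y, pol in img.micropattern_centers:
            key = (np.sign(y - x), np.sign(y + x), pol)
            counts[key] = counts.get(key, 0) + 1
        for side in (1, -1):
            for pol in (1, -1):
                assert counts[(side, 1, pol)] == counts[(side, -1, pol)]

    def test_rms_contrast_scales_with_sqrt_micropattern_count(self):
        # doubling sqrt(n_p) (16 -> 64) should double RMS contrast
        r16 = np.mean([rms_contrast(make_ltb(LTBSpec(n_p=16, pi_U=0.5, seed=s)))
                       for s in range(25)])
        r64 = np.mean([rms_contrast(make_ltb(LTBSpec(n_p=64, pi_U=0.5, seed=s)))
                       for s in range(25)])
        assert r64 / r16 == pytest.approx(2.0, rel=0.03)

    def test_placement_failure_raises(self):
        with pytest.raises(PlacementError):
            make_ltb(LTBSpec(n_p=64, pi_U=0.5, image_size=96, taper_width=8.0,
                             seed=0))


class TestSpecValidation:
    def test_pi_u_snaps_to_feasible_multiple(self):
        assert snap_pi_u(0.31, 32) == pytest.approx(0.25)
        assert snap_pi_u(0.3, 16) == pytest.approx(0.25)
        img = make_ltb(LTBSpec(n_p=32, pi_U=0.3, seed=0))
        assert img.meta["pi_U"] == pytest.approx(0.25)

    def test_snap_disabled_rejects_infeasible(self):
        with pytest.raises(ValueError, match="multiple of 4"):
            LTBSpec(n_p=32, pi_U=0.3, snap=False).validate()

    @pytest.mark.parametrize("bad", [
        dict(A=0.0), dict(A=0.6), dict(pi_U=1.5), dict(n_p=30),
        dict(orientation="vertical"), dict(phase=90)])
    def test_invalid_ltb_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            LTBSpec(**bad).validate()

    def test_invalid_lsb_contrast_rejected(self):
        with pytest.raises(ValueError):
            LSBSpec(c_M=1.2).validate()


class TestLSB:
    def test_zero_contrast_is_uniform_midgray(self, uniform_disc):
        assert np.all(uniform_disc.pixels == 0.5)

    def test_phase_is_180_degree_rotation(self):
        a = make_lsb(LSBSpec(c_M=0.02, phase=0))
        b = make_lsb(LSBSpec(c_M=0.02, phase=180))
        assert np.allclose(a.pixels, b.pixels[::-1, ::-1], atol=1e-15)

    def test_michelson_contrast_matches_spec(self, lsb_default):
        assert lsb_default.michelson_contrast() == pytest.approx(0.02, abs=1e-12)

    def test_contrast_ladder_levels(self):
        ladder = lsb_contrast_ladder()
        assert len(ladder) == 11
        assert ladder[0] == pytest.approx(10**-2.7)
        assert ladder[-1] == pytest.approx(10**-1.7)
        assert np.allclose(np.diff(np.log10(ladder)), 0.1)

    def test_pi_ladder_levels(self):
        ladder = ltb_pi_ladder()
        assert np.allclose(ladder, np.arange(9) * 0.125)


class TestCompose:
    def test_neutral_returns_ltb_unchanged(self):
        ltb = LTBSpec(n_p=32, pi_U=0.5, seed=4)
        alone = make_ltb(ltb)
        comp = compose(CompositeSpec(ltb, None, "neu"))
        assert np.array_equal(alone.pixels, comp.pixels)

    @pytest.mark.parametrize("relation,lsb_kwargs", [
        ("neu", dict()),  # neu with an LSB present
        ("con_0", dict(orientation="left_oblique")),  # orientation mismatch
        ("con_0", dict(phase=180)),  # phase mismatch
        ("con_180", dict(phase=0)),  # phases must differ
        ("inc", dict(orientation="right_oblique")),  # must be orthogonal
    ])
    def test_inconsistent_relations_rejected(self, relation, lsb_kwargs):
        ltb = LTBSpec(orientation="right_oblique", phase=0)
        lsb = LSBSpec(c_M=0.01, orientation="right_oblique", phase=0)
        lsb = dataclasses.replace(lsb, **lsb_kwargs)
        with pytest.raises(ValueError):
            CompositeSpec(ltb, lsb, relation).validate()

    def test_incongruent_mask_adds_antidiagonal_cue(self):
        ltb = LTBSpec(n_p=32, pi_U=0.5, orientation="right_oblique", seed=6)
        lsb = LSBSpec(c_M=0.02, orientation="left_oblique", phase=0)
        fv = measure(compose(CompositeSpec(ltb, lsb, "inc")))
        assert fv.L_R > 1e-4 and fv.L_L > 1e-4

    def test_opposite_phase_mask_cancels_boundary_cue(self):
        ltb = LTBSpec(n_p=32, pi_U=0.5, orientation="right_oblique", phase=0,
                      seed=6)
        con0 = compose(CompositeSpec(
            ltb, LSBSpec(c_M=0.005, orientation="right_oblique", phase=0),
            "con_0"))
        con180 = compose(CompositeSpec(
            ltb, LSBSpec(c_M=0.005, orientation="right_oblique", phase=180),
            "con_180"))
        assert measure(con180).L_R < measure(con0).L_R

    def test_clipping_is_counted(self):
        ltb = LTBSpec(n_p=32, pi_U=0.5, A=0.45, seed=1)
        lsb = LSBSpec(c_M=0.5, orientation="right_oblique", phase=0)
        comp = compose(CompositeSpec(ltb, lsb, "con_0"))
        assert comp.meta["n_clipped"] > 0
        assert comp.pixels.max() <= 1.0 and comp.pixels.min() >= 0.0


class TestIO:
    def test_png_sidecar_roundtrip(self, tmp_path):
        spec = LTBSpec(n_p=16, pi_U=0.5, image_size=128, taper_width=8.0,
                       seed=11)
        img = make_ltb(spec)
        base = tmp_path / "stim"
        save_stimulus(img, base)
        assert (tmp_path / "stim.png").exists()
        assert (tmp_path / "stim.json").exists()
        again = load_stimulus(base)
        assert np.array_equal(img.pixels, again.pixels)

    def test_png_is_16bit(self, tmp_path):
        from PIL import Image

        img = make_ltb(LTBSpec(n_p=16, pi_U=0.5, image_size=128,
                               taper_width=8.0, seed=1))
        save_stimulus(img, tmp_path / "s")
        loaded = np.asarray(Image.open(tmp_path / "s.png"))
        assert loaded.dtype == np.uint16
        assert loaded.max() > 255  # uses the 16-bit range
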