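"""Observer models: transducers, one-stage decisions, DOG filters, and the
two-stage cascade (including a brute-force pixel-level oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr, ndtri

from ltbseg import (FeatureVector, IC1Params, IC2Params, SDTParams, build_dog,
                    dc_response, ic1_prob_R, ic_sdt_dprime, ic2_prob_R,
                    make_ltb, LTBSpec, sdt_pc)
from ltbseg.models import (IC2Engine, dc_balance_rho, ic_sdt_pc, ic1_decision,
                           _gaussian2d)
from ltbseg.stimulus import LSBSpec, StimulusImage

from _oracles import brute_force_ic2_u, toy_image


class TestSDT:
    def test_zero_level_gives_chance(self):
        assert sdt_pc(0.0, SDTParams(g=2.0, tau=1.7)) == pytest.approx(0.5)

    def test_unit_transducer_argument(self):
        # g*x = 1 makes d' = 1 for any tau, so P_C = Phi(0.5)
        for tau in (0.5, 1.0, 3.0):
            assert sdt_pc(0.5, SDTParams(g=2.0, tau=tau)) == pytest.approx(
                ndtr(0.5), abs=1e-12)

    def test_lapse_ceiling(self):
        assert sdt_pc(1e6, SDTParams(g=1.0, tau=1.0, lam=0.1)) == pytest.approx(
            0.95, abs=1e-9)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            sdt_pc(-0.1, SDTParams(g=1.0, tau=1.0))

    @given(st.floats(0.01, 5.0), st.floats(0.3, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_strictly_increasing_in_level(self, g, tau):
        x = np.linspace(0.0, 2.0, 50)
        pc = sdt_pc(x, SDTParams(g=g, tau=tau))
        diffs = np.diff(pc)
        unsaturated = pc[1:] < 1.0 - 1e-12  # Phi saturates in float64
        assert np.all(diffs[unsaturated] > 0)
        assert np.all(diffs >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SDTParams(g=-1.0, tau=1.0)
        with pytest.raises(ValueError):
            SDTParams(g=1.0, tau=1.0, lam=0.2)


class TestICSDT:
    def test_zero_normalization_gain_reduces_to_additive(self):
        p_div = IC1Params(g1=3.0, p1=1.4, g2=0.0, tau2=2.0)
        L, C = 0.3, 0.8
        assert ic_sdt_dprime(L, C, p_div) == pytest.approx(
            (3.0 * L) ** 1.4, abs=1e-14)

    def test_zero_luminance_difference_gives_chance(self):
        p = IC1Params(g1=3.0, p1=1.0, g2=1.0, tau2=1.0)
        assert ic_sdt_dprime(0.0, 0.5, p) == 0.0
        assert float(ic_sdt_pc(0.0, 0.5, p)) == pytest.approx(0.5)

    def test_unit_numerator_and_denominator(self):
        # g1 L = 1, tau1 = 1, g2 C = 1, tau2 = 1  ->  d' = 1 / (1 + 1)
        p = IC1Params(g1=2.0, p1=1.0, g2=4.0, tau2=1.0)
        assert ic_sdt_dprime(0.5, 0.25, p) == pytest.approx(0.5)

    def test_dprime_decreasing_in_contrast(self):
        p = IC1Params(g1=3.0, p1=1.2, g2=2.0, tau2=1.5)
        C = np.linspace(0.0, 2.0, 40)
        d = ic_sdt_dprime(0.4, C, p)
        assert np.all(np.diff(d) < 0)


class TestIC1:
    def test_symmetric_features_give_chance(self):
        p = IC1Params(g1=5.0, p1=1.3)
        assert ic1_prob_R(FeatureVector(0.2, 0.2, 0.5), p) == pytest.approx(0.5)

    def test_mirror_antisymmetry(self):
        p = IC1Params(g1=5.0, p1=0.8, g2=1.0, tau2=1.0)
        fv = FeatureVector(0.3, 0.1, 0.6)
        swapped = FeatureVector(0.1, 0.3, 0.6)
        assert ic1_prob_R(fv, p) == pytest.approx(1 - ic1_prob_R(swapped, p),
                                                  abs=1e-12)

    def test_ic_sdt_is_special_case_on_balanced_stimuli(self):
        """With no anti-diagonal cue, the one-stage P(correct) equals the
        IC-SDT psychometric function after the gain mapping g_sdt =
        2^(1/p1) * g1 (the factor absorbs the d'/2 halving)."""
        g1, p1 = 4.0, 1.6
        ic1 = IC1Params(g1=g1, p1=p1)
        sdt_like = IC1Params(g1=2 ** (1 / p1) * g1, p1=p1)
        for L in (0.05, 0.2, 0.7):
            fv = FeatureVector(L_R=L, L_L=0.0, C=0.5)
            assert ic1_prob_R(fv, ic1) == pytest.approx(
                float(ic_sdt_pc(L, 0.5, sdt_like)), abs=1e-12)


class TestDOG:
    def test_zero_surround_is_pure_center_gaussian(self):
        k = build_dog(0.0, sigma_c=4.0)
        assert np.allclose(k.weights, _gaussian2d(4.0, 16))

    def test_dc_response_sign_change_brackets_balance(self):
        assert dc_response(build_dog(0.25)) > 0
        assert dc_response(build_dog(0.35)) < 0
        rho_bal = dc_balance_rho()
        assert 0.25 < rho_bal < 0.35
        assert dc_response(build_dog(rho_bal)) == pytest.approx(0.0, abs=1e-9)

    def test_dc_response_strictly_decreasing_in_rho(self):
        vals = [dc_response(build_dog(r)) for r in np.linspace(0, 0.6, 13)]
        assert np.all(np.diff(vals) < 0)

    def test_off_channel_dc_is_negated_on_dc(self):
        # the OFF kernel is the negated ON kernel, so its response to a
        # uniform unit input is minus the ON DC response
        k = build_dog(0.2)
        assert float((-k.weights).sum()) == pytest.approx(-dc_response(k))

    def test_surround_sd_twice_center(self):
        k = build_dog(0.2, sigma_c=3.0, support_halfwidth=12)
        assert k.sigma_s == 6.0

    def test_too_small_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            build_dog(0.3, sigma_c=4.0, support_halfwidth=10)


class TestIC2:
    def test_uniform_disc_gives_chance(self, uniform_disc):
        p = IC2Params(rho_IE=0.3, p1=2.0, p2=1.0, g2=5.0)
        assert ic2_prob_R(uniform_disc, p) == pytest.approx(0.5)

    def test_decision_matches_brute_force_oracle(self):
        """FFT-based cascade agrees with explicit pixel loops to 1e-10."""
        sigma_c, hw = 2.0, 8
        image = toy_image(blobs=((40, 14, 0.2), (20, 44, -0.15)))
        engine = IC2Engine(image.image_size, image.resolved_disc_radius(),
                           sigma_c=sigma_c, support_halfwidth=hw)
        for params in (IC2Params(rho_IE=0.0, p1=1.0, p2=1.0, g2=1.0),
                       IC2Params(rho_IE=0.25, p1=2.0, p2=1.3, g2=3.0)):
            pools = engine.channel_pools(image, params.rho_IE, params.p1)
            u_fast = engine.decision(pools, params)
            u_slow = brute_force_ic2_u(image, params, sigma_c, hw)
            assert u_fast == pytest.approx(u_slow, abs=1e-10)

    def test_mirror_antisymmetry(self, ltb_small):
        p = IC2Params(rho_IE=0.27, p1=2.0, p2=1.0, g2=8.0)
        mirrored = StimulusImage(ltb_small.pixels[:, ::-1],
                                 ltb_small.disc_mask[:, ::-1], ltb_small.spec)
        assert ic2_prob_R(ltb_small, p) == pytest.approx(
            1.0 - ic2_prob_R(mirrored, p), abs=1e-7)

    def test_balanced_first_stage_ignores_uniform_offset(self):
        """At the DC-balance point the cascade is blind to a uniform
        luminance pedestal (stimulus kept clear of the frame border, where
        the finite frame would truncate the offset's kernel support)."""
        sigma_c, hw = 2.0, 8
        rho_bal = dc_balance_rho(sigma_c, hw)
        p = IC2Params(rho_IE=rho_bal, p1=2.0, p2=1.0, g2=8.0)
        img = toy_image(blobs=((28, 38, 0.2), (36, 25, -0.2), (40, 38, 0.15)))
        shifted = StimulusImage(img.pixels + 0.01, img.disc_mask, img.spec)
        a = ic2_prob_R(img, p, sigma_c=sigma_c, support_halfwidth=hw)
        b = ic2_prob_R(shifted, p, sigma_c=sigma_c, support_halfwidth=hw)
        assert b == pytest.approx(a, abs=1e-6)

    def test_polarity_inversion_swaps_on_and_off_pools(self, ltb_small):
        engine = IC2Engine(ltb_small.image_size,
                           ltb_small.resolved_disc_radius())
        inverted = StimulusImage(1.0 - ltb_small.pixels, ltb_small.disc_mask,
                                 ltb_small.spec)
        a = engine.channel_pools(ltb_small, 0.25, 1.5)
        b = engine.channel_pools(inverted, 0.25, 1.5)
        assert a.L_R_ON == pytest.approx(b.L_R_OFF, abs=1e-10)
        assert a.L_L_OFF == pytest.approx(b.L_L_ON, abs=1e-10)

    def test_pool_then_rectify_order_is_available(self, ltb_small):
        p = IC2Params(rho_IE=0.2, p1=1.0, p2=1.0, g2=5.0)
        a = ic2_prob_R(ltb_small, p, order="rectify_then_pool")
        b = ic2_prob_R(ltb_small, p, order="pool_then_rectify")
        assert 0.0 <= b <= 1.0 and a != b

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            IC2Params(rho_IE=-0.1, p1=1.0, p2=1.0, g2=1.0)
        with pytest.raises(ValueError):
            IC2Params(rho_IE=0.2, p1=0.0, p2=1.0, g2=1.0)
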