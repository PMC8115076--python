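"""Observer decision models, from a bare SDT transducer to a two-stage
filter-rectify-filter cascade.

Four models are implemented:

* **SDT** -- proportion correct at stimulus level ``x`` is
  ``P_C = lambda/2 + (1 - lambda) * Phi(d'/2)`` with the power-law transducer
  ``d' = (g x)^tau``.
* **IC-SDT** -- the same psychometric function driven by the measured
  luminance difference ``L`` across the target diagonal, optionally divided
  by a contrast-normalization term: ``d' = (g1 L)^tau1 / (1 + (g2 C)^tau2)``.
  Setting ``g2 = 0`` recovers the additive form.
* **IC-1** -- a one-stage left/right decision model:
  ``P(R) = Phi(u)`` with ``u = (g1 L_R)^p1 - (g1 L_L)^p1`` (each term
  optionally divided by the same normalization denominator).  On stimuli with
  zero anti-diagonal luminance difference it reduces exactly to IC-SDT.
* **IC-2** -- a two-stage cascade: the image (as deviation from mid-gray) is
  convolved with ON- and OFF-center difference-of-Gaussians filters, the
  outputs are half-wave rectified and raised to an exponent ``p1``, pooled
  uniformly over the two half-discs of each diagonal, and the four resulting
  channel responses are combined as
  ``u = (g2 L_R_ON)^p2 + (g2 L_R_OFF)^p2 - (g2 L_L_ON)^p2 - (g2 L_L_OFF)^p2``,
  ``P(R) = Phi(u)``.

The DOG surround-to-center amplitude ratio ``rho_IE`` controls the filter's
response to uniform light (its DC response); the zero crossing for the
default discrete support lies near ``rho_IE ~ 0.27``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import ndtr

from ltbseg.features import FeatureVector
from ltbseg.stimulus import StimulusImage, diagonal_coords, _coords

__all__ = [
    "SDTParams", "IC1Params", "IC2Params", "DOGKernel", "ChannelPools",
    "sdt_pc", "ic_sdt_dprime", "ic1_decision", "ic1_prob_R",
    "build_dog", "dc_response", "IC2Engine", "ic2_prob_R",
]


# ---------------------------------------------------------------------------
# parameter records

@dataclass(frozen=True)
class SDTParams:
    """Gain, transducer exponent, and optional lapse rate of the SDT model."""

    g: float
    tau: float
    lam: float = 0.0

    def __post_init__(self):
        if self.g <= 0 or self.tau <= 0:
            raise ValueError("g and tau must be positive")
        if not 0.0 <= self.lam <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")


@dataclass(frozen=True)
class IC1Params:
    """Parameters of the one-stage models (IC-SDT and IC-1).

    ``g2 = 0`` disables divisive contrast normalization, reducing the divisive
    form to the additive one.
    """

    g1: float
    p1: float
    g2: float = 0.0
    tau2: float = 1.0
    lam: float = 0.0

    def __post_init__(self):
        if self.g1 <= 0 or self.p1 <= 0:
            raise ValueError("g1 and p1 must be positive")
        if self.g2 < 0:
            raise ValueError("g2 must be non-negative")
        if not 0.0 <= self.lam <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")


@dataclass(frozen=True)
class IC2Params:
    """Free parameters of the two-stage cascade."""

    rho_IE: float
    p1: float
    p2: float
    g2: float

    def __post_init__(self):
        if self.rho_IE < 0:
            raise ValueError("rho_IE must be non-negative")
        if self.p1 <= 0 or self.p2 <= 0 or self.g2 <= 0:
            raise ValueError("p1, p2, g2 must be positive")


@dataclass(frozen=True)
class ChannelPools:
    """Pooled, rectified first-stage responses per diagonal and polarity."""

    L_R_ON: float
    L_R_OFF: float
    L_L_ON: float
    L_L_OFF: float


# ---------------------------------------------------------------------------
# one-stage models

def sdt_pc(x, params: SDTParams):
    """SDT psychometric function: proportion correct at stimulus level(s) x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("stimulus level must be non-negative")
    dprime = np.power(params.g * x, params.tau)
    pc = params.lam / 2 + (1 - params.lam) * ndtr(dprime / 2)
    return float(pc) if pc.ndim == 0 else pc


def ic_sdt_dprime(L, C, params: IC1Params):
    """Image-computable d': ``(g1 L)^p1 / (1 + (g2 C)^tau2)``.

    With ``g2 = 0`` the denominator is 1 and the additive form is recovered.
    Feeds ``Phi(d'/2)`` exactly as the level-based SDT model does.
    """
    L = np.asarray(L, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(L < 0) or np.any(C < 0):
        raise ValueError("L and C must be non-negative")
    num = np.power(params.g1 * L, params.p1)
    den = 1.0 + np.power(params.g2 * C, params.tau2)
    out = num / den
    return float(out) if out.ndim == 0 else out


def ic_sdt_pc(L, C, params: IC1Params):
    """Proportion correct of the IC-SDT model (with lapse if set)."""
    d = ic_sdt_dprime(L, C, params)
    return params.lam / 2 + (1 - params.lam) * ndtr(np.asarray(d) / 2)


def ic1_decision(features: FeatureVector, params: IC1Params) -> float:
    """Decision variable ``u = (g1 L_R)^p1 - (g1 L_L)^p1`` (normalized form
    divides both terms by ``1 + (g2 C)^tau2``)."""
    den = 1.0 + (params.g2 * features.C) ** params.tau2
    return ((params.g1 * features.L_R) ** params.p1
            - (params.g1 * features.L_L) ** params.p1) / den


def ic1_prob_R(features: FeatureVector, params: IC1Params) -> float:
    """Probability of a right-oblique response, ``Phi(u)``, with lapse if set."""
    p = float(ndtr(ic1_decision(features, params)))
    return params.lam / 2 + (1 - params.lam) * p


# ---------------------------------------------------------------------------
# DOG first stage

@dataclass(frozen=True)
class DOGKernel:
    """Discrete difference-of-Gaussians filter (unit-amplitude Gaussians)."""

    rho_IE: float
    sigma_c: float
    sigma_s: float
    support_halfwidth: int
    weights: np.ndarray


def _gaussian2d(sigma: float, halfwidth: int) -> np.ndarray:
    u = np.arange(-halfwidth, halfwidth + 1)
    return np.exp(-(u[:, None] ** 2 + u[None, :] ** 2) / (2.0 * sigma**2))


def build_dog(rho_IE: float, sigma_c: float = 4.0,
              support_halfwidth: int = 16) -> DOGKernel:
    """ON-center DOG kernel ``h = c - rho_IE * s`` with ``sigma_s = 2 sigma_c``.

    The surround SD is fixed at twice the center SD; the center SD defaults to
    the micropattern radius (4 px).  The OFF kernel is the negation.
    """
    if rho_IE < 0:
        raise ValueError("rho_IE must be non-negative")
    sigma_s = 2.0 * sigma_c
    if support_halfwidth < 2 * sigma_s:
        raise ValueError(
            f"support_halfwidth={support_halfwidth} too small; "
            f"needs >= 2 * sigma_s = {2 * sigma_s}")
    c = _gaussian2d(sigma_c, support_halfwidth)
    s = _gaussian2d(sigma_s, support_halfwidth)
    return DOGKernel(rho_IE, sigma_c, sigma_s, support_halfwidth, c - rho_IE * s)


def dc_response(kernel: DOGKernel) -> float:
    """Response to uniform unit input: the sum of the kernel weights.

    Positive for small ``rho_IE`` (net-excitatory receptive field), negative
    for large; strictly decreasing in ``rho_IE``.
    """
    return float(kernel.weights.sum())


def dc_balance_rho(sigma_c: float = 4.0, support_halfwidth: int = 16) -> float:
    """The ``rho_IE`` at which the DOG's DC response vanishes (~0.27 for the
    default support)."""
    c = _gaussian2d(sigma_c, support_halfwidth)
    s = _gaussian2d(2.0 * sigma_c, support_halfwidth)
    return float(c.sum() / s.sum())


# ---------------------------------------------------------------------------
# IC-2 two-stage cascade

class IC2Engine:
    """Precomputed machinery for the two-stage model at a fixed geometry.

    The second stage integrates uniformly over the two half-planes of each
    diagonal (the whole frame, diagonal pixels excluded).  Because the
    first-stage response is zero outside the disc and its kernel-width
    neighborhood, this equals uniform half-disc integration over any disc
    containing the response support, up to a constant denominator absorbed by
    the gain ``g2``; restricting the pool to a smaller disc would instead
    truncate rim micropatterns' responses asymmetrically and inject spurious
    anti-diagonal channel noise that the balanced stimulus construction is
    designed to exclude.  Convolution uses zero padding, which is exact here
    since the true background deviation is zero.

    Because the DOG is linear in ``rho_IE`` (``h = c - rho s``), the engine
    convolves each image with the center and surround Gaussians once and
    forms the response for any ``rho_IE`` as a linear combination -- this is
    what makes grid profiling over ``rho_IE`` cheap during fitting.

    ``order`` selects where the first-stage rectification acts:
    ``"rectify_then_pool"`` (default) applies half-wave rectification and the
    exponent ``p1`` pointwise before pooling; ``"pool_then_rectify"`` pools
    the signed filter output per half-disc first and rectifies the pooled
    means.
    """

    def __init__(self, image_size: int, disc_radius: Optional[float] = None,
                 sigma_c: float = 4.0, support_halfwidth: int = 16,
                 order: str = "rectify_then_pool"):
        from ltbseg.stimulus import default_disc_radius

        if order not in ("rectify_then_pool", "pool_then_rectify"):
            raise ValueError(f"unknown rectification order {order!r}")
        self.image_size = image_size
        self.disc_radius = (disc_radius if disc_radius is not None
                            else default_disc_radius(image_size))
        self.sigma_c = sigma_c
        self.support_halfwidth = support_halfwidth
        self.order = order

        self._c = _gaussian2d(sigma_c, support_halfwidth)
        self._s = _gaussian2d(2.0 * sigma_c, support_halfwidth)

        d_right, d_left = diagonal_coords(image_size)
        pool = np.ones((image_size, image_size), dtype=bool)
        self.pool_mask = pool
        # flat indices into the pooled-pixel vector for each (diagonal, half)
        flat_d_right = d_right[pool]
        flat_d_left = d_left[pool]
        self._halves = {
            ("R", +1): flat_d_right > 0, ("R", -1): flat_d_right < 0,
            ("L", +1): flat_d_left > 0, ("L", -1): flat_d_left < 0,
        }

    # -- convolution ------------------------------------------------------

    def conv_cs(self, image: StimulusImage) -> tuple[np.ndarray, np.ndarray]:
        """Center- and surround-Gaussian convolutions of the mid-gray
        deviation image, restricted to the pool, as flat vectors."""
        dev = image.pixels - 0.5
        conv_c = fftconvolve(dev, self._c, mode="same")
        conv_s = fftconvolve(dev, self._s, mode="same")
        return conv_c[self.pool_mask], conv_s[self.pool_mask]

    def response(self, image: StimulusImage, rho_IE: float) -> np.ndarray:
        """ON-channel DOG response over the pool (OFF is the negation)."""
        conv_c, conv_s = self.conv_cs(image)
        return conv_c - rho_IE * conv_s

    # -- pooling ----------------------------------------------------------

    def pools_from_response(self, v: np.ndarray, p1: float) -> ChannelPools:
        """Channel pools from a flat ON-channel response vector."""
        on = np.maximum(v, 0.0)
        off = np.maximum(-v, 0.0)
        out = {}
        for diag in ("R", "L"):
            hp, hm = self._halves[(diag, +1)], self._halves[(diag, -1)]
            if self.order == "rectify_then_pool":
                on_p1 = on**p1
                off_p1 = off**p1
                out[f"L_{diag}_ON"] = abs(float(on_p1[hp].mean() - on_p1[hm].mean()))
                out[f"L_{diag}_OFF"] = abs(float(off_p1[hp].mean() - off_p1[hm].mean()))
            else:
                mp, mm = float(v[hp].mean()), float(v[hm].mean())
                out[f"L_{diag}_ON"] = abs(max(mp, 0.0)**p1 - max(mm, 0.0)**p1)
                out[f"L_{diag}_OFF"] = abs(max(-mp, 0.0)**p1 - max(-mm, 0.0)**p1)
        return ChannelPools(**out)

    def channel_pools(self, image: StimulusImage, rho_IE: float,
                      p1: float) -> ChannelPools:
        return self.pools_from_response(self.response(image, rho_IE), p1)

    # -- decision ---------------------------------------------------------

    @staticmethod
    def decision(pools: ChannelPools, params: IC2Params) -> float:
        g2, p2 = params.g2, params.p2
        return ((g2 * pools.L_R_ON) ** p2 + (g2 * pools.L_R_OFF) ** p2
                - (g2 * pools.L_L_ON) ** p2 - (g2 * pools.L_L_OFF) ** p2)

    def prob_R(self, image: StimulusImage, params: IC2Params) -> float:
        pools = self.channel_pools(image, params.rho_IE, params.p1)
        return float(ndtr(self.decision(pools, params)))


_ENGINE_CACHE: dict[tuple, IC2Engine] = {}


def get_engine(image_size: int, disc_radius: Optional[float] = None,
               sigma_c: float = 4.0, support_halfwidth: int = 16,
               order: str = "rectify_then_pool") -> IC2Engine:
    """Memoized :class:`IC2Engine` lookup keyed on geometry."""
    key = (image_size, disc_radius, sigma_c, support_halfwidth, order)
    if key not in _ENGINE_CACHE:
        _ENGINE_CACHE[key] = IC2Engine(image_size, disc_radius, sigma_c,
                                       support_halfwidth, order)
    return _ENGINE_CACHE[key]


def ic2_prob_R(image: StimulusImage, params: IC2Params,
               sigma_c: float = 4.0, support_halfwidth: int = 16,
               order: str = "rectify_then_pool") -> float:
    """Probability of a right-oblique response under the two-stage model."""
    engine = get_engine(image.image_size, image.resolved_disc_radius(),
                        sigma_c, support_halfwidth, order)
    return engine.prob_R(image, params)
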