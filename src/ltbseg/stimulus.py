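"""Synthesis of luminance texture boundary (LTB) and luminance step boundary
(LSB) disc stimuli, and their masked superpositions.

All stimuli live on an ``image_size`` x ``image_size`` grid of dimensionless
luminance in [0, 1] with a mid-gray background of 0.5.  A boundary is an
oblique line through the image center, either left-oblique (-45 deg from
vertical) or right-oblique (+45 deg).  An LTB carries the segmentation cue in
the relative proportions of white (luminance increment) and black (decrement)
Gaussian micropatterns on the two sides of the boundary, parameterized by the
proportion ``pi_U`` of "unbalanced" micropatterns -- those without a
same-polarity counterpart on the opposite side.  An LSB is a step edge of
Michelson contrast ``c_M`` multiplied by a cosine-tapered disc.

Construction guarantees two exact identities used throughout the test suite:

* the luminance difference across the *anti-diagonal* (the diagonal
  perpendicular to the boundary) is exactly zero, because micropatterns are
  allocated in equal per-polarity counts to the two quadrants of each side and
  no micropattern footprint is allowed to touch either diagonal;
* the Michelson contrast of a pure LTB equals ``2 * A`` exactly, because
  micropattern footprints are kept far enough apart that no pixel ever sums
  contributions above the single-pattern peak ``A``.

Coordinate convention: ``x`` increases with column, ``y`` with decreasing row,
origin at the image center ``(N - 1) / 2``.  The right-oblique diagonal is the
line ``y = x`` (signed coordinate ``d = y - x``), the left-oblique diagonal is
``y = -x`` (``d = y + x``); both signed coordinates are integers on this grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

LEFT_OBLIQUE = "left_oblique"
RIGHT_OBLIQUE = "right_oblique"
ORIENTATIONS = (LEFT_OBLIQUE, RIGHT_OBLIQUE)

#: Half-width of the (2k+1) x (2k+1) truncated-Gaussian micropattern support.
#: With sigma = 2 px this gives an "8 pixel" (diameter) blob truncated at 2 sigma.
SUPPORT_RADIUS = 4

#: Minimum Euclidean center-to-center distance between micropatterns.  One
#: footprint diameter: no pattern's support can contain another's center pixel,
#: so pixel extrema are exactly 0.5 +/- A and the Michelson identity c_M = 2A
#: holds exactly.
EXCLUSION_DISTANCE = 8.0

#: Placement attempts per micropattern before generation is declared infeasible.
MAX_ATTEMPTS = 10_000


def default_disc_radius(image_size: int) -> float:
    """Disc radius leaving a 4-px margin to the frame (124 px at 256)."""
    return image_size / 2 - 4


def _center(image_size: int) -> float:
    return (image_size - 1) / 2


def _coords(image_size: int):
    """Return (X, Y) pixel-centered coordinates, origin at the image center."""
    c = _center(image_size)
    y, x = np.mgrid[0:image_size, 0:image_size]
    return x - c, c - y


def diagonal_coords(image_size: int):
    """Signed integer coordinates across the two diagonals.

    Returns ``(d_right, d_left)`` where ``d_right = y - x`` vanishes on the
    right-oblique (+45 deg) line and ``d_left = y + x`` on the left-oblique
    line.  Pixels with a zero coordinate lie exactly on that diagonal.
    """
    X, Y = _coords(image_size)
    return np.rint(Y - X).astype(int), np.rint(Y + X).astype(int)


def radial_taper(image_size: int, disc_radius: float, taper_width: float) -> np.ndarray:
    """Raised-cosine disc window: 1 inside, cosine falloff over the outer rim."""
    X, Y = _coords(image_size)
    r = np.hypot(X, Y)
    inner = disc_radius - taper_width
    t = np.clip((r - inner) / taper_width, 0.0, 1.0)
    w = 0.5 * (1.0 + np.cos(np.pi * t))
    w[r > disc_radius] = 0.0
    w[r <= inner] = 1.0
    return w


def micropattern_kernel(sigma: float = 2.0, support_radius: int = SUPPORT_RADIUS) -> np.ndarray:
    """Unit-peak Gaussian blob truncated to a square support."""
    u = np.arange(-support_radius, support_radius + 1)
    g = np.exp(-(u[:, None] ** 2 + u[None, :] ** 2) / (2.0 * sigma**2))
    return g


def ltb_pi_ladder(n_levels: int = 9) -> np.ndarray:
    """Evenly spaced pi_U levels from 0 to 1 (default: steps of 0.125)."""
    return np.linspace(0.0, 1.0, n_levels)


def lsb_contrast_ladder(n_levels: int = 11, log10_lo: float = -2.7,
                        log10_hi: float = -1.7) -> np.ndarray:
    """Logarithmically spaced Michelson-contrast levels for the step boundary."""
    return np.logspace(log10_lo, log10_hi, n_levels)


def snap_pi_u(pi_U: float, n_p: int) -> float:
    """Snap pi_U to the nearest feasible value.

    The number of unbalanced micropatterns per side, ``pi_U * n_p``, must be a
    whole multiple of 4 so that each quadrant receives equal counts.  Ties are
    rounded up.
    """
    n_u = int(np.floor(pi_U * n_p / 4 + 0.5)) * 4
    n_u = min(max(n_u, 0), n_p)
    return n_u / n_p


@dataclass(frozen=True)
class LTBSpec:
    """Recipe for a luminance texture boundary stimulus.

    Parameters
    ----------
    n_p
        Micropatterns per side of the boundary (multiple of 4; 16/32/64 are
        the standard densities, 32 the default).
    pi_U
        Proportion of unbalanced micropatterns per side, in [0, 1].  Snapped
        to the nearest multiple of ``4 / n_p`` unless ``snap=False``.
    A
        Micropattern peak amplitude about mid-gray, in (0, 0.5].
    sigma_mp
        Micropattern Gaussian SD in pixels.
    orientation
        Boundary orientation, ``"left_oblique"`` or ``"right_oblique"``.
    phase
        0 or 180; selects which half of the disc carries the white majority.
    image_size
        Frame size in pixels.
    seed
        RNG seed for micropattern placement; same spec + seed is bit-identical.
    disc_radius, taper_width
        Disc geometry; radius defaults to ``image_size / 2 - 4``.
    snap
        If False, reject (rather than snap) infeasible ``pi_U``.
    """

    n_p: int = 32
    pi_U: float = 0.5
    A: float = 0.25
    sigma_mp: float = 2.0
    orientation: str = RIGHT_OBLIQUE
    phase: int = 0
    image_size: int = 256
    seed: int = 0
    disc_radius: Optional[float] = None
    taper_width: float = 16.0
    snap: bool = True

    def resolved_disc_radius(self) -> float:
        return (self.disc_radius if self.disc_radius is not None
                else default_disc_radius(self.image_size))

    def validate(self) -> "LTBSpec":
        if self.n_p <= 0 or self.n_p % 4 != 0:
            raise ValueError(f"n_p must be a positive multiple of 4, got {self.n_p}")
        if not 0.0 <= self.pi_U <= 1.0:
            raise ValueError(f"pi_U must lie in [0, 1], got {self.pi_U}")
        if not 0.0 < self.A <= 0.5:
            raise ValueError(f"A must lie in (0, 0.5], got {self.A}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.phase not in (0, 180):
            raise ValueError("phase must be 0 or 180")
        snapped = snap_pi_u(self.pi_U, self.n_p)
        if not self.snap and abs(snapped - self.pi_U) > 1e-12:
            raise ValueError(
                f"pi_U={self.pi_U} infeasible for n_p={self.n_p} "
                f"(pi_U * n_p must be a multiple of 4); nearest is {snapped}")
        return dataclasses.replace(self, pi_U=snapped)


@dataclass(frozen=True)
class LSBSpec:
    """Recipe for a cosine-tapered luminance step boundary."""

    c_M: float = 0.01
    orientation: str = RIGHT_OBLIQUE
    phase: int = 0
    image_size: int = 256
    disc_radius: Optional[float] = None
    taper_width: float = 16.0

    def resolved_disc_radius(self) -> float:
        return (self.disc_radius if self.disc_radius is not None
                else default_disc_radius(self.image_size))

    def validate(self) -> "LSBSpec":
        if not 0.0 <= self.c_M <= 1.0:
            raise ValueError(f"c_M must lie in [0, 1], got {self.c_M}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.phase not in (0, 180):
            raise ValueError("phase must be 0 or 180")
        return self


#: Masking relations: texture alone, congruent in-phase, congruent
#: opposite-phase, or an orthogonally oriented step boundary.
RELATIONS = ("neu", "con_0", "con_180", "inc")


@dataclass(frozen=True)
class CompositeSpec:
    """Texture target plus optional masking step boundary.

    ``relation`` encodes the masking condition and must be consistent with the
    component specs: congruent relations require equal orientations (with
    equal phases for ``con_0`` and opposite phases for ``con_180``), the
    incongruent relation requires orthogonal orientations, and ``neu`` means
    no masker at all.
    """

    ltb: LTBSpec
    lsb: Optional[LSBSpec] = None
    relation: str = "neu"

    def validate(self) -> "CompositeSpec":
        if self.relation not in RELATIONS:
            raise ValueError(f"relation must be one of {RELATIONS}")
        if self.relation == "neu":
            if self.lsb is not None:
                raise ValueError("relation 'neu' requires no LSB component")
            return CompositeSpec(self.ltb.validate(), None, "neu")
        if self.lsb is None:
            raise ValueError(f"relation {self.relation!r} requires an LSB component")
        ltb, lsb = self.ltb.validate(), self.lsb.validate()
        if lsb.image_size != ltb.image_size:
            raise ValueError("LTB and LSB image sizes must match")
        same_orient = lsb.orientation == ltb.orientation
        same_phase = lsb.phase == ltb.phase
        if self.relation == "inc":
            if same_orient:
                raise ValueError("relation 'inc' requires orthogonal orientations")
        else:
            if not same_orient:
                raise ValueError("congruent relations require equal orientations")
            if self.relation == "con_0" and not same_phase:
                raise ValueError("relation 'con_0' requires equal phases")
            if self.relation == "con_180" and same_phase:
                raise ValueError("relation 'con_180' requires opposite phases")
        return CompositeSpec(ltb, lsb, self.relation)


@dataclass
class StimulusImage:
    """A rendered stimulus: luminance array plus generation metadata.

    Attributes
    ----------
    pixels
        ``image_size`` x ``image_size`` float64 luminance in [0, 1].
    disc_mask
        Boolean mask of the tapered-disc interior (radius <= disc radius).
    spec
        The validated generating spec (LTBSpec, LSBSpec, or CompositeSpec).
    micropattern_centers
        ``(x, y, polarity)`` records in centered coordinates; empty for LSBs.
    meta
        Free-form generation metadata (snapped pi_U, clipped-pixel count, ...).
    """

    pixels: np.ndarray
    disc_mask: np.ndarray
    spec: object
    micropattern_centers: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def image_size(self) -> int:
        return self.pixels.shape[0]

    def resolved_disc_radius(self) -> float:
        return self.spec.ltb.resolved_disc_radius() if isinstance(
            self.spec, CompositeSpec) else self.spec.resolved_disc_radius()

    def michelson_contrast(self) -> float:
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        return (hi - lo) / (hi + lo)


class PlacementError(RuntimeError):
    """Micropattern placement failed within the attempt budget."""


def _boundary_antidiag(image_size: int, orientation: str):
    """Signed boundary and anti-diagonal coordinates for an orientation."""
    d_right, d_left = diagonal_coords(image_size)
    if orientation == RIGHT_OBLIQUE:
        return d_right, d_left
    return d_left, d_right


def make_ltb(spec: LTBSpec) -> StimulusImage:
    """Render a luminance texture boundary.

    Each side of the boundary receives ``n_p`` micropatterns: ``pi_U * n_p``
    unbalanced ones whose polarity is the side's majority color (white on the
    bright side, black on the dark side) and the remainder split equally
    between white and black.  Every polarity class is itself split equally
    between the two quadrants of its side, and no footprint touches either
    diagonal, so the luminance difference across the anti-diagonal is exactly
    zero.  Placement is sequential with an exclusion distance preventing any
    footprint overlap; it is deterministic given ``spec.seed``.
    """
    spec = spec.validate()
    n = spec.image_size
    R = spec.resolved_disc_radius()
    rng = np.random.default_rng(spec.seed)

    d_b, d_a = _boundary_antidiag(n, spec.orientation)
    X, Y = _coords(n)
    r = np.hypot(X, Y)

    # Centers must keep every support pixel strictly off both diagonals
    # (|d| >= support span + 1 at the center, since d shifts by at most
    # 2 * SUPPORT_RADIUS across the support) and clear of the taper.
    margin = 2 * SUPPORT_RADIUS + 1
    r_max = R - spec.taper_width - SUPPORT_RADIUS
    admissible = (np.abs(d_b) >= margin) & (np.abs(d_a) >= margin) & (r <= r_max)

    kernel = micropattern_kernel(spec.sigma_mp)
    n_u = int(round(spec.pi_U * spec.n_p))
    n_b = spec.n_p - n_u  # balanced, half white half black per side

    bright = 1 if spec.phase == 0 else -1  # sign of d_b on the white-majority side

    # (side, quadrant) -> list of polarities to place there
    plan: dict[tuple[int, int], list[int]] = {}
    for side in (1, -1):
        majority = 1 if side == bright else -1
        for quad in (1, -1):
            pols = [majority] * (n_u // 2) + [1] * (n_b // 4) + [-1] * (n_b // 4)
            plan[(side, quad)] = pols

    cand_idx = {}
    for side in (1, -1):
        for quad in (1, -1):
            ok = admissible & (np.sign(d_b) == side) & (np.sign(d_a) == quad)
            rows, cols = np.nonzero(ok)
            if len(rows) == 0:
                raise PlacementError("no admissible micropattern locations; "
                                     "disc too small for this geometry")
            cand_idx[(side, quad)] = (rows, cols)

    placed_xy: list[tuple[float, float]] = []
    centers: list[tuple[float, float, int]] = []
    canvas = np.zeros((n, n))
    c0 = _center(n)
    sr = SUPPORT_RADIUS

    for key, pols in plan.items():
        rows, cols = cand_idx[key]
        for pol in pols:
            for _ in range(MAX_ATTEMPTS):
                i = rng.integers(len(rows))
                rr, cc = int(rows[i]), int(cols[i])
                x, y = cc - c0, c0 - rr
                if placed_xy:
                    pts = np.asarray(placed_xy)
                    if np.min(np.hypot(pts[:, 0] - x, pts[:, 1] - y)) < EXCLUSION_DISTANCE:
                        continue
                break
            else:
                raise PlacementError(
                    f"could not place micropattern after {MAX_ATTEMPTS} attempts "
                    f"(n_p={spec.n_p} too dense for image_size={n})")
            placed_xy.append((x, y))
            centers.append((x, y, pol))
            canvas[rr - sr:rr + sr + 1, cc - sr:cc + sr + 1] += pol * spec.A * kernel

    pixels = 0.5 + canvas
    disc_mask = r <= R
    meta = {"pi_U_requested": spec.pi_U, "pi_U": spec.pi_U,
            "n_unbalanced_per_side": n_u, "n_balanced_per_side": n_b,
            "n_clipped": 0}
    return StimulusImage(pixels, disc_mask, spec, centers, meta)


def make_lsb(spec: LSBSpec) -> StimulusImage:
    """Render a cosine-tapered luminance step boundary.

    Luminance is ``0.5 * (1 +/- c_M * taper(r))`` on the two halves; phase 180
    is the 180-degree rotation of phase 0, and the pixel extrema inside the
    full-amplitude region give Michelson contrast exactly ``c_M``.
    """
    spec = spec.validate()
    n = spec.image_size
    R = spec.resolved_disc_radius()
    d_b, _ = _boundary_antidiag(n, spec.orientation)
    X, Y = _coords(n)
    r = np.hypot(X, Y)
    taper = radial_taper(n, R, spec.taper_width)
    sgn = 1.0 if spec.phase == 0 else -1.0
    pixels = 0.5 * (1.0 + sgn * spec.c_M * np.sign(d_b) * taper)
    return StimulusImage(pixels, r <= R, spec, [], {"n_clipped": 0})


def compose(spec: CompositeSpec) -> StimulusImage:
    """Superimpose a texture target and a masking step boundary.

    Deviations from mid-gray add; the result is clipped to [0, 1] with the
    clipped-pixel count recorded in ``meta``.  ``relation="neu"`` returns the
    texture stimulus unchanged.
    """
    spec = spec.validate()
    ltb_img = make_ltb(spec.ltb)
    if spec.relation == "neu":
        ltb_img.spec = spec
        ltb_img.meta["relation"] = "neu"
        return ltb_img
    lsb_img = make_lsb(spec.lsb)
    raw = 0.5 + (ltb_img.pixels - 0.5) + (lsb_img.pixels - 0.5)
    pixels = np.clip(raw, 0.0, 1.0)
    n_clipped = int(np.count_nonzero(raw != pixels))
    meta = dict(ltb_img.meta)
    meta.update({"n_clipped": n_clipped, "relation": spec.relation})
    return StimulusImage(pixels, ltb_img.disc_mask, spec,
                         ltb_img.micropattern_centers, meta)


def make_stimulus(spec) -> StimulusImage:
    """Dispatch on spec type (LTBSpec / LSBSpec / CompositeSpec)."""
    if isinstance(spec, LTBSpec):
        return make_ltb(spec)
    if isinstance(spec, LSBSpec):
        return make_lsb(spec)
    if isinstance(spec, CompositeSpec):
        return compose(spec)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


# ---------------------------------------------------------------------------
# serialization

def _spec_to_dict(spec) -> dict:
    if isinstance(spec, CompositeSpec):
        return {"type": "CompositeSpec", "relation": spec.relation,
                "ltb": _spec_to_dict(spec.ltb),
                "lsb": None if spec.lsb is None else _spec_to_dict(spec.lsb)}
    d = dataclasses.asdict(spec)
    d["type"] = type(spec).__name__
    return d


def spec_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type")
    if kind == "CompositeSpec":
        lsb = d["lsb"]
        return CompositeSpec(spec_from_dict(d["ltb"]),
                             None if lsb is None else spec_from_dict(lsb),
                             d["relation"])
    cls = {"LTBSpec": LTBSpec, "LSBSpec": LSBSpec}[kind]
    return cls(**d)


def save_stimulus(image: StimulusImage, path) -> None:
    """Write a 16-bit grayscale PNG plus a JSON sidecar with full metadata."""
    from PIL import Image

    path = Path(path)
    arr = np.clip(np.rint(image.pixels * 65535), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(path.with_suffix(".png"))
    sidecar = {
        "spec": _spec_to_dict(image.spec),
        "meta": image.meta,
        "micropattern_centers": [[float(x), float(y), int(p)]
                                 for x, y, p in image.micropattern_centers],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stimulus(path) -> StimulusImage:
    """Regenerate a stimulus from its JSON sidecar (bit-identical by seed)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return make_stimulus(spec_from_dict(sidecar["spec"]))
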