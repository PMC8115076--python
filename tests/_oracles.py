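"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the library's convolution/pooling code paths:
explicit Python loops over pixels and kernel taps, so they can serve as an
independent check of the two-stage cascade.
"""

import numpy as np

from ltbseg.stimulus import LSBSpec, StimulusImage


def toy_image(n=64, blobs=((40, 14, 0.2),)):
    """Tiny stimulus with point-like deviations at given (row, col, dev)."""
    pixels = np.full((n, n), 0.5)
    for r, c, dev in blobs:
        pixels[r, c] += dev
    x, y = np.mgrid[0:n, 0:n]
    mask = np.hypot(x - (n - 1) / 2, y - (n - 1) / 2) <= n / 2 - 4
    return StimulusImage(pixels, mask,
                         LSBSpec(image_size=n, disc_radius=n / 2 - 4))


def brute_force_ic2_u(image, params, sigma_c, hw):
    """Explicit-loop reimplementation of the two-stage decision variable
    (rectify-then-pool order)."""
    n = image.image_size
    dev = image.pixels - 0.5
    u_ax = np.arange(-hw, hw + 1)
    r2 = u_ax[:, None] ** 2 + u_ax[None, :] ** 2
    kern = (np.exp(-r2 / (2 * sigma_c**2))
            - params.rho_IE * np.exp(-r2 / (2 * (2 * sigma_c) ** 2)))
    resp = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for di in range(-hw, hw + 1):
                for dj in range(-hw, hw + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < n:
                        acc += dev[ii, jj] * kern[hw + di, hw + dj]
            resp[i, j] = acc
    c0 = (n - 1) / 2
    y, x = np.mgrid[0:n, 0:n]
    X, Y = x - c0, c0 - y
    pools = {}
    for name, d in (("R", Y - X), ("L", Y + X)):
        hp, hm = d > 0.5, d < -0.5
        for label, v in (("ON", resp), ("OFF", -resp)):
            rect = np.maximum(v, 0.0) ** params.p1
            pools[f"{name}_{label}"] = abs(rect[hp].mean() - rect[hm].mean())
    return ((params.g2 * pools["R_ON"]) ** params.p2
            + (params.g2 * pools["R_OFF"]) ** params.p2
            - (params.g2 * pools["L_ON"]) ** params.p2
            - (params.g2 * pools["L_OFF"]) ** params.p2)
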