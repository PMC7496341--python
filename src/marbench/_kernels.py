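"""Numba kernels for parallel-beam forward projection and backprojection.

Forward projection is ray-driven (Joseph-style): each detector ray is
marched in steps of one pixel with bilinear sampling of the image.
Backprojection is pixel-driven with linear interpolation in the detector
coordinate.  Both use the convention of `phantom.pixel_grid`: pixel
centers, x right, y up, row 0 at the top.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_project(image, pixel_size, cos_t, sin_t, n_bins, spacing, support_radius):
    """support_radius > 0 bounds the integration to the circle where the
    image is known to be nonzero (the phantom support); <= 0 integrates the
    full grid diagonal."""
    n = image.shape[0]
    n_views = cos_t.shape[0]
    sino = np.zeros((n_views, n_bins))
    half = (n - 1) / 2.0
    bin_half = (n_bins - 1) / 2.0
    full_ext = 0.5 * n * pixel_size * np.sqrt(2.0)
    for v in range(n_views):
        c, s = cos_t[v], sin_t[v]
        for b in range(n_bins):
            sb = (b - bin_half) * spacing
            if support_radius > 0.0:
                h2 = support_radius * support_radius - sb * sb
                if h2 <= 0.0:
                    continue
                ext = np.sqrt(h2)
            else:
                ext = full_ext
            n_steps = int(2.0 * ext / pixel_size) + 1
            x0 = sb * c
            y0 = sb * s
            acc = 0.0
            for k in range(n_steps):
                t = -ext + k * pixel_size
                x = x0 - t * s
                y = y0 + t * c
                # bilinear sample at (x, y)
                fj = x / pixel_size + half
                fi = half - y / pixel_size
                j0 = int(np.floor(fj))
                i0 = int(np.floor(fi))
                if j0 < 0 or j0 >= n - 1 or i0 < 0 or i0 >= n - 1:
                    continue
                dx = fj - j0
                dy = fi - i0
                acc += (
                    image[i0, j0] * (1.0 - dx) * (1.0 - dy)
                    + image[i0, j0 + 1] * dx * (1.0 - dy)
                    + image[i0 + 1, j0] * (1.0 - dx) * dy
                    + image[i0 + 1, j0 + 1] * dx * dy
                )
            sino[v, b] = acc * pixel_size
    return sino


@njit(cache=True)
def backproject(filtered, cos_t, sin_t, spacing, out_size, pixel_size):
    n_views, n_bins = filtered.shape
    out = np.zeros((out_size, out_size))
    half = (out_size - 1) / 2.0
    bin_half = (n_bins - 1) / 2.0
    for v in range(n_views):
        c, s = cos_t[v], sin_t[v]
        row = filtered[v]
        for i in range(out_size):
            y = -(i - half) * pixel_size
            for j in range(out_size):
                x = (j - half) * pixel_size
                u = (x * c + y * s) / spacing + bin_half
                i0 = int(np.floor(u))
                if i0 < 0 or i0 >= n_bins - 1:
                    continue
                f = u - i0
                out[i, j] += row[i0] * (1.0 - f) + row[i0 + 1] * f
    out *= np.pi / n_views
    return out
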