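"""Numba kernels for the hot path of ellipse-probe optimization.

Scalar point-to-ellipse signed distance (same bracketed-bisection scheme as
:func:`ellipore.ellipsoid.signed_ellipse_distance`) plus a minimum-clearance
reduction over atom discs with two prunings: a triangle-inequality lower
bound per disc, and an optional early exit once the running minimum drops
below a caller-supplied threshold (used by feasibility bisection, where
only the sign relative to the tolerance matters).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _signed_dist(px, py, a, b, iters):
    px = abs(px)
    py = abs(py)
    tiny = 1e-10 * b
    if px < tiny:
        px = 0.0
    if py < tiny:
        py = 0.0
    c2 = a * a - b * b
    inside = (px / a) ** 2 + (py / b) ** 2 < 1.0
    if px == 0.0 and py == 0.0:
        return -b  # center of the ellipse
    if py == 0.0 and px * a <= c2 and c2 > 0.0:
        cx = a * a * px / c2
        t = 1.0 - (cx / a) ** 2
        cy = b * np.sqrt(t if t > 0.0 else 0.0)
        d = np.hypot(px - cx, cy)
    else:
        apx = a * px
        bpy = b * py
        lo = bpy
        hi = np.hypot(apx, bpy)
        if hi <= lo:
            hi = lo + 1e-30
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            t1 = apx / (mid + c2)
            t2 = bpy / mid if mid > 0.0 else 0.0
            if t1 * t1 + t2 * t2 - 1.0 > 0.0:
                lo = mid
            else:
                hi = mid
        u = 0.5 * (lo + hi)
        cx = a * a * px / (u + c2)
        cy = b * b * py / u if u > 0.0 else 0.0
        d = np.hypot(px - cx, py - cy)
    return -d if inside else d


@njit(cache=True)
def min_clearance(centers, rho, ex, ey, a, b, theta, stop_below, iters):
    """min over discs of signed distance minus rho; early exit below threshold."""
    ct = np.cos(theta)
    st = np.sin(theta)
    best = np.inf
    for i in range(centers.shape[0]):
        dx = centers[i, 0] - ex
        dy = centers[i, 1] - ey
        # lower bound: dist(point, ellipse) >= |point| - a
        lb = np.hypot(dx, dy) - a - rho[i]
        if lb >= best:
            continue
        px = ct * dx + st * dy
        py = -st * dx + ct * dy
        cl = _signed_dist(px, py, a, b, iters) - rho[i]
        if cl < best:
            best = cl
            if best < stop_below:
                return best
    return best
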