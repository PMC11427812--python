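"""Scalar summaries of pore profiles: areas, volumes, effective radii.

Volumes use the stacked-slab rule V = sum_i pi * a_i * b_i * dz over the
finite, unflagged slices — the same discretization the resistance model
uses — so the ellipsoidal/spherical volume ratio is a direct measure of
how much cross-section a spherical probe misses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ellipore.pathfinder import SphericalProfile
from ellipore.ellipsoid import EllipsoidProfile, ProbeEllipse


@dataclass
class PoreSummary:
    z_range: tuple
    volume_sphere: float
    volume_ellipse: float
    volume_ratio: float
    min_b: float
    min_b_z: float
    min_a: float
    min_a_z: float

    def to_dict(self) -> dict:
        return {
            "z_range": [float(self.z_range[0]), float(self.z_range[1])],
            "volume_sphere_A3": self.volume_sphere,
            "volume_ellipse_A3": self.volume_ellipse,
            "volume_ratio": self.volume_ratio,
            "min_b_A": self.min_b, "min_b_z_A": self.min_b_z,
            "min_a_A": self.min_a, "min_a_z_A": self.min_a_z,
        }


def _profile_arrays(profile):
    """(z, a, b, usable, dz) for either profile kind."""
    if isinstance(profile, EllipsoidProfile):
        z, a, b = profile.zs, profile.a, profile.b
        flagged = profile.flagged
        dz = profile.dz
    elif isinstance(profile, SphericalProfile):
        z, a = profile.zs, profile.radii
        b = a
        flagged = ~profile.usable
        dz = profile.dz
    else:
        raise TypeError(f"unsupported profile type {type(profile)!r}")
    usable = ~flagged & np.isfinite(a) & np.isfinite(b)
    return z, a, b, usable, dz


def default_z_range(profile) -> tuple[float, float]:
    """Maximal contiguous run of usable slices containing the global min b.

    This is the "pore proper": integration bounds chosen deterministically
    around the narrowest constriction, excluding the unbounded mouths.
    """
    z, _, b, usable, _ = _profile_arrays(profile)
    if not usable.any():
        raise ValueError("profile has no usable slices")
    idx = np.where(usable)[0]
    imin = idx[np.argmin(b[idx])]
    lo = imin
    while lo - 1 >= 0 and usable[lo - 1]:
        lo -= 1
    hi = imin
    while hi + 1 < len(z) and usable[hi + 1]:
        hi += 1
    return float(z[lo]), float(z[hi])


def pore_volume(profile, z_range=None) -> float:
    """Slab-rule pore volume (A^3) over ``z_range`` (default: pore proper)."""
    z, a, b, usable, dz = _profile_arrays(profile)
    if z_range is None:
        z_range = default_z_range(profile)
    zmin, zmax = min(z_range), max(z_range)
    sel = usable & (z >= zmin - 1e-9) & (z <= zmax + 1e-9)
    if sel.sum() < 2:
        raise ValueError("need at least 2 usable slices inside z_range")
    return float(np.sum(np.pi * a[sel] * b[sel]) * dz)


def capsule_effective_radius(r: float, Lc: float) -> float:
    """Area-equivalent radius of a spherocylinder cross-section.

    A capsule of radius r whose centers sit a distance Lc apart has
    in-plane area pi r^2 + 2 r Lc; the circle of equal area has radius
    sqrt(r^2 + 2 Lc r / pi).
    """
    if r <= 0 or Lc < 0:
        raise ValueError("need r > 0 and Lc >= 0")
    return float(np.sqrt(r * r + 2.0 * Lc * r / np.pi))


def eccentricity(ellipse_or_a, b: float | None = None) -> float:
    """e = sqrt(1 - b^2/a^2); 0 for a circle, -> 1 for extreme elongation."""
    if isinstance(ellipse_or_a, ProbeEllipse):
        a, b = ellipse_or_a.a, ellipse_or_a.b
    else:
        a = float(ellipse_or_a)
    if not (a >= b > 0):
        raise ValueError("need a >= b > 0")
    return float(np.sqrt(1.0 - (b / a) ** 2))


def summarize(spherical: SphericalProfile, ellipsoidal: EllipsoidProfile,
              z_range=None) -> PoreSummary:
    """Joint summary of the two profiles over a common z range."""
    if z_range is None:
        z_range = default_z_range(ellipsoidal)
    vs = pore_volume(spherical, z_range)
    ve = pore_volume(ellipsoidal, z_range)
    z, a, b, usable, _ = _profile_arrays(ellipsoidal)
    sel = usable & (z >= min(z_range) - 1e-9) & (z <= max(z_range) + 1e-9)
    ib = np.where(sel)[0][np.argmin(b[sel])]
    ia = np.where(sel)[0][np.argmin(a[sel])]
    return PoreSummary(
        z_range=(min(z_range), max(z_range)),
        volume_sphere=vs, volume_ellipse=ve, volume_ratio=ve / vs,
        min_b=float(b[ib]), min_b_z=float(z[ib]),
        min_a=float(a[ia]), min_a_z=float(z[ia]),
    )
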