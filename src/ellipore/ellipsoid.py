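"""Inflation of spherical probes into maximal in-plane ellipses.

Each slice's sphere (radius r) becomes an ellipse with semi-axes a >= b,
center (x, y) and orientation theta, where b is pinned to r and a is
maximized subject to non-overlap with the atoms' van der Waals spheres.
In the slice plane each atom of radius r_atom at height offset dz reduces
to a disc of radius rho = sqrt(r_atom^2 - dz^2); the non-overlap
constraint is then a signed point-to-ellipse distance test per disc.

Optimization is staged Nelder-Mead over [x, y, a, theta]: a first pass
with tight bounds, a second with wider ones, each followed by a
feasibility restore that shrinks a until the clearance tolerance holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from ellipore.structure import AtomSet
from ellipore.pathfinder import ProbeSphere, SphericalProfile, DEFAULT_END_RADIUS

log = logging.getLogger(__name__)

#: overlap penalty weight (1/A) in the staged objective
PENALTY = 1.0e4
#: clearance tolerance (A): ellipses may violate by at most this much
CLEARANCE_TOL = 1.0e-3
_DIST_ITER = 60  # bisection iterations for point-to-ellipse distance
_FAST_ITER = 36  # reduced precision (<1e-9 A at slice scales) inside optimizers


@dataclass
class AtomDisc:
    """In-plane cross-section of an atom sphere: 2-D center + radius rho (A)."""

    center: np.ndarray
    rho: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not self.rho > 0:
            raise ValueError("disc radius must be > 0")


@dataclass
class ProbeEllipse:
    """Per-slice ellipse: center (2-D, A), semi-axes a >= b (A), theta in [0, pi)."""

    center: np.ndarray
    a: float
    b: float
    theta: float
    z: float
    flagged: bool = False

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")
        self.theta = float(self.theta) % np.pi

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.b / self.a) ** 2))

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)


@dataclass
class EllipsoidProfile:
    """Ellipse per slice, z-matched to its companion spherical profile."""

    slices: list
    spherical: SphericalProfile

    def __post_init__(self):
        if len(self.slices) != len(self.spherical):
            raise ValueError("slice count must match the spherical profile")

    @property
    def dz(self) -> float:
        return self.spherical.dz

    @property
    def zs(self) -> np.ndarray:
        return np.array([e.z for e in self.slices])

    @property
    def a(self) -> np.ndarray:
        return np.array([e.a for e in self.slices])

    @property
    def b(self) -> np.ndarray:
        return np.array([e.b for e in self.slices])

    @property
    def theta(self) -> np.ndarray:
        return np.array([e.theta for e in self.slices])

    @property
    def flagged(self) -> np.ndarray:
        return np.array([e.flagged for e in self.slices])

    def __len__(self) -> int:
        return len(self.slices)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "z": self.zs,
            "x": [e.center[0] for e in self.slices],
            "y": [e.center[1] for e in self.slices],
            "a": self.a, "b": self.b,
            "theta_deg": np.degrees(self.theta),
            "eccentricity": [e.eccentricity for e in self.slices],
            "flagged": self.flagged,
        })


def atom_discs(z: float, atoms: AtomSet) -> list[AtomDisc]:
    """Discs cut by the plane ``z = const`` through the atom spheres.

    An atom contributes iff ``|z_atom - z| < r_atom`` (open interval, so
    rho is strictly positive).
    """
    dz = atoms.positions[:, 2] - z
    mask = np.abs(dz) < atoms.radii
    rho = np.sqrt(atoms.radii[mask] ** 2 - dz[mask] ** 2)
    xy = atoms.positions[mask, :2]
    return [AtomDisc(center=c, rho=r) for c, r in zip(xy, rho)]


def _disc_arrays(discs) -> tuple[np.ndarray, np.ndarray]:
    if len(discs) == 0:
        return np.empty((0, 2)), np.empty(0)
    return (np.stack([d.center for d in discs]),
            np.array([d.rho for d in discs]))


def signed_ellipse_distance(points: np.ndarray, a: float, b: float,
                            iters: int = _DIST_ITER) -> np.ndarray:
    """Signed distance from 2-D points to the axis-aligned ellipse boundary.

    Positive outside the ellipse, negative inside; computed to better than
    1e-6 A by safeguarded bisection on the rational root equation of the
    closest-point parameter (monotone in the substitution u = t + b^2, so
    the bracket is guaranteed).  Vectorized over points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    px = np.abs(pts[:, 0])
    py = np.abs(pts[:, 1])
    a = float(a)
    b = float(b)
    c2 = a * a - b * b  # >= 0 since a >= b
    # sub-threshold coordinates are zeroed: the root bracket otherwise
    # underflows for points numerically on an axis or at the center
    tiny = 1e-10 * b
    px = np.where(px < tiny, 0.0, px)
    py = np.where(py < tiny, 0.0, py)

    inside = (px / a) ** 2 + (py / b) ** 2 < 1.0
    dist = np.empty(len(pts))

    # general branch: root u* of (a px/(u+c2))^2 + (b py/u)^2 = 1 in
    # [b*py, hypot(a px, b py)]; closest point follows from u*.
    s = np.hypot(a * px, b * py)
    general = (py > 0) | (px * a > c2)  # off-axis, or on-axis beyond the evolute
    g = np.where(general)[0]
    if len(g) > 0:
        lo = b * py[g]
        hi = np.maximum(s[g], lo + 1e-30)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            f = ((a * px[g] / (mid + c2)) ** 2
                 + np.divide(b * py[g], mid, out=np.zeros_like(mid),
                             where=mid > 0) ** 2) - 1.0
            take_hi = f > 0
            lo = np.where(take_hi, mid, lo)
            hi = np.where(take_hi, hi, mid)
        u = 0.5 * (lo + hi)
        cx = a * a * px[g] / (u + c2)
        cy = np.divide(b * b * py[g], u, out=np.full_like(u, 0.0), where=u > 0)
        dist[g] = np.hypot(px[g] - cx, py[g] - cy)

    # on the major axis inside the evolute: closest point is off-axis
    special = ~general
    sp = np.where(special)[0]
    if len(sp) > 0:
        if c2 == 0:
            dist[sp] = b - np.hypot(px[sp], py[sp])
        else:
            cx = a * a * px[sp] / c2
            cy = b * np.sqrt(np.maximum(0.0, 1.0 - (cx / a) ** 2))
            dist[sp] = np.hypot(px[sp] - cx, cy)

    return np.where(inside, -np.abs(dist), np.abs(dist))


def ellipse_clearance(ellipse: ProbeEllipse, discs) -> float:
    """Minimum over discs of (signed distance to ellipse boundary - rho).

    Negative when any disc overlaps the ellipse; ``+inf`` for no discs.
    """
    centers, rho = _disc_arrays(discs)
    if len(centers) == 0:
        return np.inf
    return float(np.min(_clearances(
        centers, rho, ellipse.center, ellipse.a, ellipse.b, ellipse.theta,
        iters=_DIST_ITER)))


def _clearances(centers, rho, exy, a, b, theta,
                iters: int = _FAST_ITER) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    d = centers - exy
    local = np.column_stack([ct * d[:, 0] + st * d[:, 1],
                             -st * d[:, 0] + ct * d[:, 1]])
    return signed_ellipse_distance(local, a, b, iters=iters) - rho


def _min_clearance(centers, rho, exy, a, b, theta,
                   stop_below: float = -np.inf) -> float:
    """Kernel-backed min clearance; early exit once below ``stop_below``."""
    from ellipore._kernels import min_clearance

    return min_clearance(np.ascontiguousarray(centers, dtype=np.float64),
                         np.ascontiguousarray(rho, dtype=np.float64),
                         float(exy[0]), float(exy[1]), float(a), float(b),
                         float(theta), stop_below, _FAST_ITER)


def max_feasible_a(xy, theta, b, discs, a_hi, tol: float = 1e-4) -> float:
    """Largest semi-major axis a in [b, a_hi] with clearance >= -CLEARANCE_TOL.

    The ellipse is nested-increasing in a, so clearance is non-increasing
    in a and bisection is exact.
    """
    centers, rho = _disc_arrays(discs)
    if len(centers) == 0:
        return a_hi

    stop = -CLEARANCE_TOL - 1e-9

    def ok(a):
        return _min_clearance(centers, rho, xy, a, b, theta,
                              stop_below=stop) >= -CLEARANCE_TOL

    if not ok(b):
        return b
    if ok(a_hi):
        return a_hi
    lo, hi = b, a_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _canonical(xy, a, b, theta, z, flagged=False) -> ProbeEllipse:
    if a < b:
        a, b = b, a
        theta += 0.5 * np.pi
    return ProbeEllipse(center=xy, a=a, b=b, theta=theta % np.pi, z=z,
                        flagged=flagged)


def expand_slice(sphere: ProbeSphere, discs,
                 end_radius: float = DEFAULT_END_RADIUS) -> ProbeEllipse:
    """Inflate one slice's sphere into a maximal in-plane ellipse.

    b is held fixed at the sphere radius throughout; [x, y, a, theta] are
    optimized in two Nelder-Mead stages (tight then wide bounds) on the
    penalized objective a - PENALTY * max(0, -clearance)^2, preceded by a
    coarse theta scan and followed by a feasibility restore (shrink a by
    bisection until clearance >= -CLEARANCE_TOL).
    """
    b = float(sphere.radius)
    z = float(sphere.center[2])
    x0 = sphere.center[:2].astype(float)
    if not np.isfinite(b) or b <= 0:
        raise ValueError("expand_slice needs a finite positive sphere radius")
    centers, rho = _disc_arrays(discs)
    if len(centers) == 0:
        r = min(b, end_radius) if np.isfinite(b) else end_radius
        return ProbeEllipse(center=x0, a=r, b=r, theta=0.0, z=z, flagged=True)

    a_cap = max(b, min(8.0 * b, end_radius))

    # coarse orientation scan: best theta for growth at the sphere center
    thetas = np.linspace(0.0, np.pi, 18, endpoint=False)
    best_th = max(thetas, key=lambda th: max_feasible_a(x0, th, b, discs,
                                                        a_cap, tol=2e-2))

    def stage(p_start, dxy, a_hi):
        """One Nelder-Mead pass; returns a feasible point with a >= p_start's."""
        lo = np.array([p_start[0] - dxy, p_start[1] - dxy, b, -4 * np.pi])
        hi = np.array([p_start[0] + dxy, p_start[1] + dxy, a_hi, 4 * np.pi])

        def neg_obj(p):
            p = np.clip(p, lo, hi)
            cl = _min_clearance(centers, rho, p[:2], p[2], b, p[3])
            # the small clearance reward breaks the plateau in the center
            # coordinates: at equal a, better-centered ellipses win, which
            # is where further growth of a is possible
            return -(p[2] + 0.05 * cl - PENALTY * max(0.0, -cl) ** 2)

        p0 = np.array([p_start[0], p_start[1],
                       max(b, min(p_start[2], a_hi)), p_start[3]])
        # perturb away from any active bound so the simplex stays full-rank
        steps = np.array([0.2 * b, 0.2 * b, 0.3 * b, 0.3])
        verts = []
        for i, d in enumerate(steps):
            v = p0.copy()
            v[i] = v[i] + d if v[i] + d <= hi[i] else v[i] - d
            verts.append(np.clip(v, lo, hi))
        simplex = np.vstack([p0] + verts)
        res = minimize(neg_obj, p0, method="Nelder-Mead",
                       options={"initial_simplex": simplex, "xatol": 1e-3,
                                "fatol": 1e-5, "maxiter": 400,
                                "maxfev": 400})
        p = np.clip(res.x, lo, hi)
        # feasibility restore: largest feasible a at the found center and
        # orientation (the penalty allows sub-tolerance overlap, and the
        # optimizer may also have stopped short of the wall)
        circle_ok = _min_clearance(centers, rho, p[:2], b, b, p[3]) \
            >= -CLEARANCE_TOL
        if circle_ok:
            a = max_feasible_a(p[:2], p[3], b, discs, a_hi)
            cand = np.array([p[0], p[1], a, p[3]])
            if cand[2] >= p_start[2]:
                return cand
        return p_start

    a_init = max_feasible_a(x0, best_th, b, discs, a_cap)
    p_init = np.array([x0[0], x0[1], min(a_init, 2.0 * b), best_th])
    p1 = stage(p_init, 0.5 * b, min(2.0 * b, a_cap))
    p2 = stage(p1, 2.0 * b, a_cap)

    # refinement: with a eliminated analytically (max_feasible_a is exact
    # given center and orientation), maximize over the remaining 3 dof —
    # this has no feasibility plateau and rescues slices where the 4-D
    # polytope collapsed early; run from both the staged result and the
    # theta-scan seed, which can sit in different orientation basins
    def neg_a(q):
        xy = np.clip(q[:2], x0 - 2.0 * b, x0 + 2.0 * b)
        return -max_feasible_a(xy, q[2], b, discs, a_cap, tol=1e-3)

    def refine(q0):
        simplex = np.vstack([q0] + [q0 + d for d in
                                    np.diag([0.3 * b, 0.3 * b, 0.3])])
        res = minimize(neg_a, q0, method="Nelder-Mead",
                       options={"initial_simplex": simplex, "xatol": 1e-3,
                                "fatol": 1e-4, "maxiter": 300,
                                "maxfev": 300})
        xy = np.clip(res.x[:2], x0 - 2.0 * b, x0 + 2.0 * b)
        a_ref = max_feasible_a(xy, res.x[2], b, discs, a_cap)
        return np.array([xy[0], xy[1], a_ref, res.x[2]])

    p3 = refine(np.array([p2[0], p2[1], p2[3]]))
    p4 = refine(np.array([x0[0], x0[1], best_th]))
    p = max((p2, p3, p4), key=lambda v: v[2])

    if p[2] <= b + 1e-9:
        return ProbeEllipse(center=x0, a=b, b=b, theta=0.0, z=z)
    return _canonical(p[:2], p[2], b, p[3], z)


def expand_profile(profile: SphericalProfile, atoms: AtomSet,
                   end_radius: float | None = None) -> EllipsoidProfile:
    """Inflate every slice of a spherical profile (slices are independent).

    Slices whose sphere is flagged (unbounded/mouth) or that cut no atom
    are carried through flagged with a = b and excluded from volume
    integration downstream.
    """
    end_radius = profile.end_radius if end_radius is None else end_radius
    out = []
    for sph in profile.slices:
        z = sph.z
        if not np.isfinite(sph.radius):
            out.append(ProbeEllipse(center=sph.center[:2], a=end_radius,
                                    b=end_radius, theta=0.0, z=z, flagged=True))
            continue
        discs = atom_discs(z, atoms)
        if sph.radius > end_radius or sph.radius <= 0 or not discs:
            # past the mouth, blocked, or nothing in the plane: carry the
            # slice through flagged so z registration is preserved
            r = max(min(sph.radius, end_radius), 1e-6)
            out.append(ProbeEllipse(center=sph.center[:2], a=r, b=r,
                                    theta=0.0, z=z, flagged=True))
            continue
        out.append(expand_slice(sph, discs, end_radius=end_radius))
    return EllipsoidProfile(slices=out, spherical=profile)
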