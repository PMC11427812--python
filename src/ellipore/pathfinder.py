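"""HOLE-style spherical probe pathway tracing.

Per z-slice, the probe center is moved within the plane to maximize its
clearance — the largest sphere radius that touches no atom's van der Waals
sphere — using Monte Carlo simulated annealing followed by a
derivative-free local polish.  Slices are walked outward from a start
point in both z directions, each seeded with the previous optimum, until
the probe radius exceeds a stop radius (the pore mouth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ellipore.structure import AtomSet

log = logging.getLogger(__name__)

#: Slice radius at which a pathway walk leaves the pore (A).
DEFAULT_END_RADIUS = 15.0
#: Slice spacing (A); fine enough to resolve constrictions.
DEFAULT_DZ = 0.25
DEFAULT_SEED = 42

# annealing schedule: 500 Gaussian proposals, step 0.5 A decaying by 0.99
# per proposal, Metropolis temperature 0.5 -> 0.005 A (geometric).
_ANNEAL_STEPS = 500
_STEP0 = 0.5
_STEP_DECAY = 0.99
_T0, _T1 = 0.5, 0.005


@dataclass
class ProbeSphere:
    """Maximal clearance sphere of one slice: center (3-vector, A), radius (A)."""

    center: np.ndarray
    radius: float
    flagged: bool = False  # True when the slice saw no atoms (unbounded)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def z(self) -> float:
        return float(self.center[2])


@dataclass
class SphericalProfile:
    """Ordered per-slice probe spheres along z with uniform spacing ``dz``."""

    slices: list
    dz: float
    start: np.ndarray = None
    end_radius: float = DEFAULT_END_RADIUS
    rng_seed: int = DEFAULT_SEED

    def __post_init__(self):
        z = self.zs
        if len(z) > 1:
            if np.any(np.diff(z) <= 0):
                raise ValueError("slice z values must be strictly increasing")
            if not np.allclose(np.diff(z), self.dz, atol=1e-9):
                raise ValueError("slice spacing must equal dz")

    @property
    def zs(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.slices])

    @property
    def centers(self) -> np.ndarray:
        return np.stack([s.center for s in self.slices])

    @property
    def flagged(self) -> np.ndarray:
        return np.array([s.flagged for s in self.slices])

    @property
    def usable(self) -> np.ndarray:
        """Slices inside the pore proper: finite radius not past the mouth.

        Boundary-constrained slices (flagged by the walk's search box) stay
        usable — their probe is valid, just pinned by pathway continuity.
        """
        r = self.radii
        return np.isfinite(r) & (r > 0) & (r <= self.end_radius)

    def __len__(self) -> int:
        return len(self.slices)

    def to_frame(self):
        import pandas as pd

        c = self.centers
        return pd.DataFrame({
            "z": c[:, 2], "x": c[:, 0], "y": c[:, 1],
            "radius": self.radii, "flagged": self.flagged,
        })


def clearance_radius(point, atoms: AtomSet) -> float:
    """Largest probe radius centered at ``point`` touching no atom sphere.

    ``min_i(|point - x_i| - r_i)``; negative when the point lies inside an
    atom's van der Waals sphere.
    """
    p = np.asarray(point, dtype=float)
    d = np.linalg.norm(atoms.positions - p, axis=1)
    return float(np.min(d - atoms.radii))


def _slab_atoms(atoms: AtomSet, z: float, end_radius: float) -> AtomSet:
    """Atoms that can constrain a probe of radius <= end_radius at height z."""
    from dataclasses import replace

    # an atom can limit a probe of radius <= end_radius in this plane only
    # if its sphere comes within end_radius of it; an empty slab means the
    # slice is unbounded and is flagged upstream.
    mask = np.abs(atoms.positions[:, 2] - z) <= (atoms.radii + end_radius)
    if mask.sum() == 0:
        return None
    return replace(atoms, positions=atoms.positions[mask],
                   radii=atoms.radii[mask], elements=atoms.elements[mask],
                   names=atoms.names[mask], resnames=atoms.resnames[mask],
                   masses=atoms.masses[mask])


DEFAULT_SLICE_BOUNDS = 2.0


def optimize_slice(z: float, seed_xy, atoms: AtomSet, rng_seed: int = DEFAULT_SEED,
                   end_radius: float = DEFAULT_END_RADIUS,
                   bounds: float | None = DEFAULT_SLICE_BOUNDS) -> ProbeSphere:
    """Maximize probe clearance in the plane ``z = const``.

    Simulated annealing (Metropolis on negative clearance) from ``seed_xy``
    followed by Nelder-Mead polish.  Deterministic given ``rng_seed``.
    ``bounds`` restricts |x|, |y| displacement from the seed: the slice
    optimum of interest is the one in the seed's pore basin, and clearance
    grows without bound outside any enclosing wall, so an unrestricted
    anneal would eventually tunnel out.  An optimum on the box boundary is
    flagged (unbounded or box-limited direction); pass ``bounds=None`` for
    a fully free search.

    Returns a flagged sphere with radius ``inf`` when no atom lies within
    reach of the plane.
    """
    seed_xy = np.asarray(seed_xy, dtype=float).reshape(2)
    local = _slab_atoms(atoms, z, end_radius)
    if local is None:
        return ProbeSphere(center=np.r_[seed_xy, z], radius=np.inf, flagged=True)

    pos = local.positions
    rad = local.radii

    def clear(xy):
        d = np.sqrt((pos[:, 0] - xy[0]) ** 2 + (pos[:, 1] - xy[1]) ** 2
                    + (pos[:, 2] - z) ** 2)
        return np.min(d - rad)

    rng = np.random.default_rng(rng_seed)
    x = seed_xy.copy()
    fx = clear(x)
    best, fbest = x.copy(), fx
    step = _STEP0
    temps = _T0 * (_T1 / _T0) ** (np.arange(_ANNEAL_STEPS) / (_ANNEAL_STEPS - 1))
    for t in temps:
        prop = x + rng.normal(scale=step, size=2)
        if bounds is not None:
            prop = np.clip(prop, seed_xy - bounds, seed_xy + bounds)
        fp = clear(prop)
        if fp >= fx or rng.random() < np.exp((fp - fx) / t):
            x, fx = prop, fp
            if fx > fbest:
                best, fbest = x.copy(), fx
        step *= _STEP_DECAY

    # polish in seed-relative coordinates so results are translation
    # equivariant (Nelder-Mead's initial simplex depends on magnitudes)
    def boxed(d):
        p = best + d
        if bounds is not None:
            p = np.clip(p, seed_xy - bounds, seed_xy + bounds)
        return p

    res = minimize(lambda d: -clear(boxed(d)), np.zeros(2),
                   method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400})
    xopt = boxed(res.x)
    if bounds is not None:
        xopt = np.clip(xopt, seed_xy - bounds, seed_xy + bounds)
    if clear(xopt) < fbest:
        xopt = best
    r = clear(xopt)
    on_boundary = bounds is not None and np.any(
        np.isclose(np.abs(xopt - seed_xy), bounds, atol=1e-6))
    if on_boundary:
        log.warning("slice z=%.2f: optimum on search boundary "
                    "(unbounded direction?)", z)
    return ProbeSphere(center=np.r_[xopt, z], radius=float(r),
                       flagged=bool(on_boundary))


def trace_pathway(atoms: AtomSet, start=None, dz: float = DEFAULT_DZ,
                  end_radius: float = DEFAULT_END_RADIUS,
                  rng_seed: int = DEFAULT_SEED,
                  max_shift: float = 1.0) -> SphericalProfile:
    """Trace the pore pathway through an aligned structure.

    Slices are generated from the start z (default: center of mass) outward
    in both directions, each seeded with the previous slice's optimal
    center; a direction stops once its slice radius exceeds ``end_radius``.
    ``max_shift`` bounds the per-slice lateral displacement of the probe
    center (A): the pathway is continuous, and an unbounded search can
    tunnel through gaps in the atom lattice and escape the pore.
    """
    start = atoms.center_of_mass if start is None else np.asarray(start, float)
    s0 = optimize_slice(start[2], start[:2], atoms, rng_seed, end_radius,
                        bounds=max_shift)
    if np.isfinite(s0.radius) and s0.radius <= 0:
        raise ValueError(
            "start point is buried (negative clearance at "
            f"z={start[2]:.2f}); supply a start point inside the pore")

    def walk(direction: int) -> list:
        out = []
        prev = s0
        k = 1
        while True:
            z = start[2] + direction * k * dz
            slice_seed = (rng_seed + 2 * k + (direction < 0)) % (2 ** 31)
            s = optimize_slice(z, prev.center[:2], atoms, slice_seed,
                               end_radius, bounds=max_shift)
            out.append(s)
            if not np.isfinite(s.radius) or s.radius > end_radius:
                break
            prev = s
            k += 1
        return out

    down = walk(-1)
    up = walk(+1)
    slices = list(reversed(down)) + [s0] + up
    return SphericalProfile(slices=slices, dz=dz, start=start,
                            end_radius=end_radius, rng_seed=rng_seed)
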