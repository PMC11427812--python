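"""Synthetic pore structures with exact ground truth.

Two families, both built from coordinates alone (no force fields, no
dynamics):

* armchair carbon nanotubes — rolled-graphene lattices whose radius is
  fixed by the chirality (n, n) and the C-C bond length, optionally
  deformed into an elliptical cross-section by the area-preserving map
  x -> x/sqrt(s), y -> y*sqrt(s) so that the semi-axis ratio equals s;
* bead-wall pores — rings of beads tracing a prescribed wall profile
  (cylinder, elliptical channel, hourglass), whose inscribed probe radius
  is known analytically (wall minus bead radius).

These are the package's test fixtures and calibration systems: every
geometric claim the probe algorithms make can be checked against the
generator's closed-form ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ellipore.structure import AtomSet, DEFAULT_RADII

CC_BOND = 1.421  # graphene C-C bond length, A
CH_BOND = 1.09  # terminal C-H bond length, A


@dataclass
class CNTSpec:
    """Armchair carbon nanotube: chirality (n, n), length L (A), ratio s = b/a."""

    n: int
    m: int = None
    length: float = 50.0
    cc_bond: float = CC_BOND
    cap_hydrogens: bool = True
    ellipticity_ratio: float = 1.0  # s = b/a in (0, 1]

    def __post_init__(self):
        if self.m is None:
            self.m = self.n
        if self.n != self.m or self.n < 4:
            raise ValueError("only armchair tubes (n = m >= 4) are supported")
        if not 0.0 < self.ellipticity_ratio <= 1.0:
            raise ValueError("ellipticity ratio s = b/a must be in (0, 1]")
        if self.length <= self.period:
            raise ValueError("length must exceed one translational period")

    @property
    def period(self) -> float:
        """Translational period along the tube axis, sqrt(3) * cc (A)."""
        return np.sqrt(3.0) * self.cc_bond

    @property
    def ideal_radius(self) -> float:
        """Roll-up radius (sqrt(3) cc / 2 pi) * sqrt(n^2 + n m + m^2) (A)."""
        return (np.sqrt(3.0) * self.cc_bond / (2.0 * np.pi)
                * np.sqrt(self.n ** 2 + self.n * self.m + self.m ** 2))

    @property
    def semi_axes(self) -> tuple[float, float]:
        """Deformed wall semi-axes (a_wall, b_wall) = (r/sqrt(s), r*sqrt(s))."""
        s = self.ellipticity_ratio
        r = self.ideal_radius
        return r / np.sqrt(s), r * np.sqrt(s)

    def ground_truth(self, carbon_radius: float = DEFAULT_RADII["C"]) -> dict:
        aw, bw = self.semi_axes
        return {
            "ideal_radius_A": self.ideal_radius,
            "wall_semi_axes_A": [aw, bw],
            "inscribed_sphere_radius_A": bw - carbon_radius,
            "inscribed_ellipse_semi_axes_A": [aw - carbon_radius,
                                              bw - carbon_radius],
            "ellipticity_ratio": self.ellipticity_ratio,
            "length_A": self.length,
            "carbon_radius_A": carbon_radius,
        }


def build_cnt(spec: CNTSpec) -> AtomSet:
    """Coordinates of an armchair CNT, axis on z, centered at the origin.

    4n carbons per translational period; optional axial terminal hydrogens
    on the first and last atom layers.  Radii are pre-assigned from the
    default table (C/H); deterministic output.
    """
    cc = spec.cc_bond
    n = spec.n
    r = spec.ideal_radius
    circumference = 3.0 * cc * n
    period = spec.period
    n_periods = max(1, int(round(spec.length / period)))

    # rectangular 4-atom graphene cell, armchair edge along the axis:
    # width 3*cc around the circumference, height sqrt(3)*cc along z
    cell = np.array([
        [0.0, 0.0],
        [cc, 0.0],
        [1.5 * cc, 0.5 * period],
        [2.5 * cc, 0.5 * period],
    ])

    sheet = []
    for j in range(n_periods):
        for k in range(n):
            for cx, cz in cell:
                sheet.append((cx + 3.0 * cc * k, cz + period * j))
    sheet = np.array(sheet)

    phi = 2.0 * np.pi * sheet[:, 0] / circumference
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), sheet[:, 1]])
    elements = ["C"] * len(pos)

    if spec.cap_hydrogens:
        zmin, zmax = pos[:, 2].min(), pos[:, 2].max()
        caps = []
        for p in pos:
            if np.isclose(p[2], zmin):
                caps.append([p[0], p[1], p[2] - CH_BOND])
            elif np.isclose(p[2], zmax):
                caps.append([p[0], p[1], p[2] + CH_BOND])
        pos = np.vstack([pos, np.array(caps)])
        elements += ["H"] * len(caps)

    pos[:, 2] -= pos[:, 2].mean()
    s = spec.ellipticity_ratio
    if s != 1.0:  # area-preserving elliptical deformation
        pos[:, 0] /= np.sqrt(s)
        pos[:, 1] *= np.sqrt(s)

    radii = np.array([DEFAULT_RADII[e] for e in elements])
    names = np.array([f"{e}{i + 1}" for i, e in enumerate(elements)],
                     dtype=object)
    return AtomSet(positions=pos, radii=radii,
                   elements=np.array(elements, dtype=object), names=names,
                   resnames=np.full(len(pos), "CNT", dtype=object))


@dataclass
class SyntheticPoreSpec:
    """Bead-wall pore: rings of beads tracing semi_axes(z) = (A(z), B(z))."""

    semi_axes: callable  # z -> (A, B) wall semi-axes in A
    length: float = 50.0
    bead_radius: float = 1.85
    beads_per_ring: int = 72
    ring_spacing: float = 1.0

    def ground_truth(self) -> dict:
        zs = np.arange(-self.length / 2, self.length / 2 + 1e-9,
                       self.ring_spacing)
        ab = np.array([self.semi_axes(z) for z in zs])
        return {
            "z_A": zs.tolist(),
            "wall_semi_axes_A": ab.tolist(),
            "inscribed_sphere_radius_A":
                (ab.min(axis=1) - self.bead_radius).tolist(),
            "bead_radius_A": self.bead_radius,
            # chord sagitta of the bead ring: worst-case radius bias
            "discretization_error_A": float(
                ab.max() * (1 - np.cos(np.pi / self.beads_per_ring))),
        }


def cylinder_spec(wall_radius: float = 10.0, **kw) -> SyntheticPoreSpec:
    return SyntheticPoreSpec(semi_axes=lambda z: (wall_radius, wall_radius),
                             **kw)


def elliptical_spec(a_wall: float = 12.0, b_wall: float = 6.0,
                    **kw) -> SyntheticPoreSpec:
    return SyntheticPoreSpec(semi_axes=lambda z: (a_wall, b_wall), **kw)


def hourglass_spec(mouth_radius: float = 10.0, waist_radius: float = 4.0,
                   length: float = 50.0, **kw) -> SyntheticPoreSpec:
    """Two cones meeting at a circular waist at z = 0."""

    def semi_axes(z):
        r = waist_radius + (mouth_radius - waist_radius) * abs(z) / (length / 2)
        return (r, r)

    return SyntheticPoreSpec(semi_axes=semi_axes, length=length, **kw)


def build_bead_pore(spec: SyntheticPoreSpec) -> AtomSet:
    """Rings of beads on the prescribed wall; analytic clearance ground truth."""
    pos = []
    zs = np.arange(-spec.length / 2, spec.length / 2 + 1e-9, spec.ring_spacing)
    angles = 2.0 * np.pi * np.arange(spec.beads_per_ring) / spec.beads_per_ring
    for z in zs:
        A, B = spec.semi_axes(z)
        if min(A, B) <= spec.bead_radius:
            raise ValueError("wall semi-axes must exceed the bead radius")
        for t in angles:
            pos.append([A * np.cos(t), B * np.sin(t), z])
    pos = np.asarray(pos)
    n = len(pos)
    return AtomSet(positions=pos, radii=np.full(n, spec.bead_radius),
                   elements=np.full(n, "C", dtype=object),
                   names=np.array([f"B{i + 1}" for i in range(n)], dtype=object),
                   resnames=np.full(n, "PORE", dtype=object),
                   masses=np.full(n, 12.011))


def write_pdb(atoms: AtomSet, path) -> None:
    """Write an AtomSet as a single-model PDB file."""
    import MDAnalysis as mda

    n = len(atoms)
    resnames = np.unique(atoms.resnames)
    resmap = {r: i for i, r in enumerate(resnames)}
    resindex = np.array([resmap[r] for r in atoms.resnames])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=len(resnames),
                               atom_resindex=resindex, trajectory=True)
        u.add_TopologyAttr("names", [str(x)[:4] for x in atoms.names])
        u.add_TopologyAttr("elements", [str(x) for x in atoms.elements])
        u.add_TopologyAttr("resnames", [str(x)[:4] for x in resnames])
        u.add_TopologyAttr("resids", np.arange(len(resnames)) + 1)
        u.atoms.positions = atoms.positions.astype(np.float32)
        u.atoms.write(str(path))


def write_ground_truth(spec, path) -> None:
    """Write the generator's analytic ground truth as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(spec.ground_truth(), fh, indent=2)
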