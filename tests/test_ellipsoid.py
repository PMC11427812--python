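"""Ellipse probe: disc reduction, clearance, slice and profile expansion."""

import numpy as np
import pytest

from ellipore import (
    AtomSet, AtomDisc, ProbeEllipse, atom_discs, ellipse_clearance,
    expand_slice, expand_profile, trace_pathway,
)
from ellipore.ellipsoid import signed_ellipse_distance, max_feasible_a
from ellipore.pathfinder import ProbeSphere


def _atoms(positions, radii):
    positions = np.atleast_2d(positions)
    n = len(positions)
    radii = np.broadcast_to(np.asarray(radii, float), (n,)).copy()
    return AtomSet(positions=positions, radii=radii,
                   elements=np.full(n, "C", dtype=object),
                   masses=np.ones(n))


class TestAtomDiscs:
    def test_in_plane_atom_keeps_full_radius(self):
        discs = atom_discs(0.0, _atoms([[1, 2, 0]], 2.0))
        assert len(discs) == 1
        assert discs[0].rho == pytest.approx(2.0)

    def test_offset_atom_shrinks(self):
        discs = atom_discs(0.0, _atoms([[0, 0, 1.0]], 2.0))
        assert discs[0].rho == pytest.approx(np.sqrt(3.0))

    def test_tangent_atom_excluded(self):
        assert atom_discs(0.0, _atoms([[0, 0, 2.0]], 2.0)) == []


def _boundary_sample_distance(point, a, b, n=1_000_000):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    d = np.min(np.hypot(a * np.cos(t) - point[0], b * np.sin(t) - point[1]))
    inside = (point[0] / a) ** 2 + (point[1] / b) ** 2 < 1
    return -d if inside else d


class TestEllipseClearance:
    def test_circle_reduces_to_disc_formula(self):
        discs = [AtomDisc(center=[4.0, 3.0], rho=1.2),
                 AtomDisc(center=[-2.0, 0.5], rho=0.7)]
        r = 2.0
        circ = ProbeEllipse(center=[0, 0], a=r, b=r, theta=0.0, z=0.0)
        expected = min(np.hypot(*d.center) - r - d.rho for d in discs)
        assert ellipse_clearance(circ, discs) == pytest.approx(expected, abs=1e-9)

    def test_disc_on_major_axis(self):
        e = ProbeEllipse(center=[0, 0], a=4.0, b=2.0, theta=0.0, z=0.0)
        discs = [AtomDisc(center=[4.0 + 3.0, 0.0], rho=1.0)]
        assert ellipse_clearance(e, discs) == pytest.approx(2.0, abs=1e-6)

    def test_empty_discs_is_unbounded(self):
        e = ProbeEllipse(center=[0, 0], a=2.0, b=1.0, theta=0.0, z=0.0)
        assert np.isinf(ellipse_clearance(e, []))

    @pytest.mark.parametrize("a,b", [(3.0, 1.0), (5.0, 4.9), (8.0, 1.2)])
    def test_signed_distance_matches_boundary_sampling(self, a, b):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-10, 10, size=(20, 2))
        got = signed_ellipse_distance(pts, a, b)
        for p, g in zip(pts, got):
            assert g == pytest.approx(_boundary_sample_distance(p, a, b),
                                      abs=1e-4)

    def test_rotated_frame(self):
        # ellipse rotated 90 deg: its major axis lies along y
        e = ProbeEllipse(center=[0, 0], a=4.0, b=2.0, theta=np.pi / 2, z=0.0)
        discs = [AtomDisc(center=[0.0, 6.0], rho=1.0)]
        assert ellipse_clearance(e, discs) == pytest.approx(1.0, abs=1e-6)


def _ring_discs(a_wall, b_wall, rho=1.85, n=72):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return [AtomDisc(center=[a_wall * np.cos(u), b_wall * np.sin(u)], rho=rho)
            for u in t]


class TestExpandSlice:
    def test_circular_wall_cannot_elongate(self):
        discs = _ring_discs(10.0, 10.0)
        sph = ProbeSphere(center=[0, 0, 0], radius=8.15)
        e = expand_slice(sph, discs)
        assert e.a - e.b < 0.1
        assert e.b == sph.radius

    def test_elliptical_wall_matches_feasibility_oracle(self):
        discs = _ring_discs(12.0, 6.0)
        sph = ProbeSphere(center=[0, 0, 0], radius=4.15)
        e = expand_slice(sph, discs)
        best = _oracle_best_a(discs, b=4.15,
                              thetas=np.radians(np.arange(0, 180, 5.0)),
                              xs=np.arange(-0.3, 0.31, 0.1), ys=(0.0,),
                              a_hi=12.0)
        assert e.a == pytest.approx(best, rel=0.05)
        assert min(e.theta, np.pi - e.theta) < np.radians(5)

    def test_slit_matches_grid_oracle(self):
        # four discs leaving free space along x
        discs = [AtomDisc(center=[0.0, 2.5], rho=1.0),
                 AtomDisc(center=[0.0, -2.5], rho=1.0),
                 AtomDisc(center=[6.0, 0.0], rho=1.0),
                 AtomDisc(center=[-6.0, 0.0], rho=1.0)]
        sph = ProbeSphere(center=[0, 0, 0], radius=1.5)
        e = expand_slice(sph, discs)
        grid = np.arange(-0.5, 0.51, 0.1)
        best = _oracle_best_a(discs, b=1.5,
                              thetas=np.radians(np.arange(0, 180, 6.0)),
                              xs=grid, ys=grid, a_hi=12.0)
        assert e.a == pytest.approx(best, abs=0.1)

    def test_canonical_orientation_and_order(self):
        discs = _ring_discs(6.0, 12.0)  # major axis along y
        sph = ProbeSphere(center=[0, 0, 0], radius=4.15)
        e = expand_slice(sph, discs)
        assert e.a >= e.b > 0
        assert 0 <= e.theta < np.pi
        assert abs(e.theta - np.pi / 2) < np.radians(5)

    def test_rotation_equivariance(self):
        sph = ProbeSphere(center=[0, 0, 0], radius=4.15)
        e0 = expand_slice(sph, _ring_discs(12.0, 6.0))
        phi = np.radians(30)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rotated = [AtomDisc(center=R @ d.center, rho=d.rho)
                   for d in _ring_discs(12.0, 6.0)]
        e1 = expand_slice(sph, rotated)
        assert e1.a == pytest.approx(e0.a, abs=0.05)
        assert e1.b == e0.b
        dth = (e1.theta - e0.theta - phi) % np.pi
        assert min(dth, np.pi - dth) < np.radians(5)


def _oracle_best_a(discs, b, thetas, xs, ys, a_hi, n_boundary=360, iters=22):
    """Grid-and-bisection oracle for the maximal semi-major axis.

    Feasibility is judged by dense boundary sampling of the candidate
    ellipse against every disc — independent of the implementation's
    point-to-ellipse distance solver.
    """
    cen = np.array([[d.center[0], d.center[1]] for d in discs])
    rho = np.array([d.rho for d in discs])
    t = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    best = b
    for th in thetas:
        for x in xs:
            for y in ys:
                if not _feasible(x, y, th, b, b, t, cen, rho):
                    continue
                lo, hi = b, a_hi
                for _ in range(iters):
                    a = 0.5 * (lo + hi)
                    if _feasible(x, y, th, a, b, t, cen, rho):
                        lo = a
                    else:
                        hi = a
                best = max(best, lo)
    return best


def _feasible(x, y, th, a, b, t, cen, rho, tol=1e-3):
    # same non-overlap tolerance as the implementation contract (-1e-3 A)
    bx = x + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
    by = y + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
    d = np.hypot(bx[:, None] - cen[None, :, 0], by[:, None] - cen[None, :, 1])
    if np.min(d - rho[None, :]) < -tol:
        return False
    # disc center inside the ellipse also counts as overlap
    ct, st = np.cos(th), np.sin(th)
    px = ct * (cen[:, 0] - x) + st * (cen[:, 1] - y)
    py = -st * (cen[:, 0] - x) + ct * (cen[:, 1] - y)
    return not np.any((px / a) ** 2 + (py / b) ** 2 < 1)


class TestExpandProfile:
    def test_b_equals_spherical_radius_exactly(self, cylinder_pipeline):
        sph, ell = cylinder_pipeline
        for s, e in zip(sph.slices, ell.slices):
            if np.isfinite(s.radius) and not e.flagged:
                assert e.b == s.radius

    def test_cylinder_stays_isotropic(self, cylinder_pipeline):
        # interior slices only: near the mouths the wall no longer encloses
        # the plane and the ellipse legitimately stretches outward
        sph, ell = cylinder_pipeline
        ok = ~ell.flagged & (np.abs(ell.zs) < 7.0)
        assert ok.sum() > 20
        assert np.all(ell.a[ok] / ell.b[ok] <= 1.05)

    def test_hourglass_minima_colocate(self, hourglass_pipeline):
        sph, ell = hourglass_pipeline
        ok = ~ell.flagged
        z = ell.zs[ok]
        za = z[np.argmin(ell.a[ok])]
        zb = z[np.argmin(ell.b[ok])]
        assert abs(za - zb) <= ell.dz + 1e-9

    def test_slice_count_matches(self, hourglass_pipeline):
        sph, ell = hourglass_pipeline
        assert len(sph) == len(ell)
        assert np.allclose(sph.zs, ell.zs)

    def test_clearance_invariant(self, bead_hourglass, hourglass_pipeline):
        atoms, _ = bead_hourglass
        _, ell = hourglass_pipeline
        for e in ell.slices:
            if e.flagged:
                continue
            discs = atom_discs(e.z, atoms)
            assert ellipse_clearance(e, discs) >= -1.5e-3
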