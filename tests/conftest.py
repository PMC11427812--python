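"""Shared fixtures: synthetic pores and full pipeline runs (session-scoped)."""

import logging

import numpy as np
import pytest

from ellipore import trace_pathway, expand_profile
from ellipore.synthetic import (
    CNTSpec, build_cnt, build_bead_pore,
    cylinder_spec, hourglass_spec, elliptical_spec,
)

logging.getLogger("ellipore").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bead_cylinder():
    """Cylinder wall radius 10 A, bead radius 1.85 A -> inscribed 8.15 A."""
    spec = cylinder_spec(wall_radius=10.0, length=20.0)
    return build_bead_pore(spec), spec


@pytest.fixture(scope="session")
def bead_hourglass():
    """Two cones meeting at a 4 A circular waist at z = 0."""
    spec = hourglass_spec(mouth_radius=10.0, waist_radius=4.0, length=30.0)
    return build_bead_pore(spec), spec


@pytest.fixture(scope="session")
def bead_elliptical():
    """Elliptical channel, wall semi-axes (12, 6) A."""
    spec = elliptical_spec(a_wall=12.0, b_wall=6.0, length=16.0)
    return build_bead_pore(spec), spec


def _pipeline(atoms):
    sph = trace_pathway(atoms)
    return sph, expand_profile(sph, atoms)


@pytest.fixture(scope="session")
def cylinder_pipeline(bead_cylinder):
    return _pipeline(bead_cylinder[0])


@pytest.fixture(scope="session")
def hourglass_pipeline(bead_hourglass):
    return _pipeline(bead_hourglass[0])


@pytest.fixture(scope="session")
def cnt_round():
    spec = CNTSpec(n=8, length=50.0, ellipticity_ratio=1.0)
    return build_cnt(spec), spec


@pytest.fixture(scope="session")
def cnt_elliptic():
    spec = CNTSpec(n=8, length=50.0, ellipticity_ratio=0.5)
    return build_cnt(spec), spec


@pytest.fixture(scope="session")
def cnt_round_pipeline(cnt_round):
    return _pipeline(cnt_round[0])


@pytest.fixture(scope="session")
def cnt_elliptic_pipeline(cnt_elliptic):
    return _pipeline(cnt_elliptic[0])


def interior_mask(profile, half_width=20.0):
    """Slices well inside the pore, away from the mouths."""
    return (np.abs(profile.zs) < half_width) & profile.usable
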