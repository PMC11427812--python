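"""Conductance heuristics for pore profiles.

A channel is modelled as a stack of elliptical cylinders of thickness dz.
With bulk electrolyte conductivity the resistance is the Ohmic series sum

    R = sum_i dz / (kappa_i * pi * a_i * b_i),      g = 1/R,

which reduces to Hille's single-cylinder R = rho L / A for a uniform
profile.  Confinement reduces ion mobility, so kappa is not bulk inside
narrow constrictions: the radius-dependent conductivity

    kappa(a, b) = sigma(a c1 - c2) * sigma(b c1 - c2) * kappa_bulk

(sigma the logistic function) interpolates between ~0 for sub-ionic radii
and kappa_bulk for wide pores.  c1 (1/A) and c2 (dimensionless) are fitted
from training records of measured conductances via the per-record observed
conductivity kappa_obs = g * L / (pi a b).

Units: geometry in A, kappa in S/m, R in ohm, g in pS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.optimize import minimize
from scipy.special import expit

A_TO_M = 1.0e-10
S_TO_PS = 1.0e12

#: KCl diffusion coefficients (m^2/s) and standard simulation conditions
DEFAULT_D_K = 1.96e-9
DEFAULT_D_CL = 2.03e-9
DEFAULT_T = 300.0
DEFAULT_C = 0.15  # mol/L


@dataclass
class BulkConductivity:
    """Nernst-Einstein bulk conductivity of a symmetric 1:1 electrolyte."""

    concentration: float  # mol/L
    temperature: float  # K
    D_K: float  # m^2/s
    D_Cl: float  # m^2/s
    kappa_bulk: float  # S/m

    @property
    def rho_bulk(self) -> float:
        """Bulk resistivity (ohm m)."""
        return 1.0 / self.kappa_bulk


def bulk_conductivity(c: float = DEFAULT_C, T: float = DEFAULT_T,
                      D_K: float = DEFAULT_D_K,
                      D_Cl: float = DEFAULT_D_CL) -> BulkConductivity:
    """kappa_bulk = q_e^2 n (D_K + D_Cl) / (k_B T), n = c N_A 10^3 m^-3."""
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    if c < 0 or D_K <= 0 or D_Cl <= 0:
        raise ValueError("concentration must be >= 0, diffusivities > 0")
    n = c * constants.Avogadro * 1.0e3  # number density per m^3
    kappa = constants.e ** 2 * n * (D_K + D_Cl) / (constants.k * T)
    return BulkConductivity(concentration=c, temperature=T, D_K=D_K,
                            D_Cl=D_Cl, kappa_bulk=kappa)


@dataclass
class ConductivityParams:
    """Double-sigmoid conductivity parameters: c1 (1/A) > 0, c2 (unitless)."""

    c1: float
    c2: float
    residual: float = float("nan")  # fit SSE on kappa (S/m)^2
    r_squared: float = float("nan")  # on conductances

    def __post_init__(self):
        if self.c1 <= 0:
            import logging

            logging.getLogger(__name__).warning(
                "fitted c1 = %.4g <= 0: conductivity would decrease with "
                "radius; check the training records", self.c1)


@dataclass
class TrainingRecord:
    """One measured system: mean radii a >= b (A), length L (A), g (pS)."""

    a: float
    b: float
    L: float
    g_MD: float

    def __post_init__(self):
        if not (self.a >= self.b > 0) or self.L <= 0 or self.g_MD < 0:
            raise ValueError(f"invalid training record {self!r}")

    @property
    def kappa_obs(self) -> float:
        """Observed conductivity g L / (pi a b) in S/m."""
        g_S = self.g_MD / S_TO_PS
        return g_S * (self.L * A_TO_M) / (np.pi * self.a * self.b * A_TO_M ** 2)


def conductivity_model(a, b, params: ConductivityParams,
                       bulk: BulkConductivity):
    """kappa(a, b) in S/m; strictly below kappa_bulk, increasing in a and b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("radii must be > 0")
    s = expit(a * params.c1 - params.c2) * expit(b * params.c1 - params.c2)
    out = s * bulk.kappa_bulk
    return float(out) if out.ndim == 0 else out


@dataclass
class ConductanceEstimate:
    R: float  # ohm
    g: float  # pS
    contributions: np.ndarray = field(repr=False)  # ohm per slice
    variant: str = "spherical-bulk"

    def to_dict(self) -> dict:
        return {"variant": self.variant, "R_ohm": self.R, "g_pS": self.g}


def _profile_geometry(profile):
    from ellipore.metrics import _profile_arrays, default_z_range

    z, a, b, usable, dz = _profile_arrays(profile)
    zmin, zmax = default_z_range(profile)
    sel = usable & (z >= zmin - 1e-9) & (z <= zmax + 1e-9)
    return z[sel], a[sel], b[sel], dz


def channel_resistance(profile, bulk: BulkConductivity,
                       params: ConductivityParams | None = None,
                       ) -> ConductanceEstimate:
    """Series resistance of the profile's slab stack; g returned in pS.

    ``params=None`` uses bulk conductivity in every slab (the classic
    spherical-probe estimate when the profile is spherical); otherwise each
    slab gets the double-sigmoid kappa(a_i, b_i).

    A slice with nonpositive radius anywhere in the profile means the
    pathway is sterically blocked (infinite series resistance) and raises.
    """
    from ellipore.pathfinder import SphericalProfile

    if isinstance(profile, SphericalProfile):
        r_all = profile.radii
        z_all = profile.zs
        bad = np.where(np.isfinite(r_all) & (r_all <= 0))[0]
        if len(bad):
            raise ValueError(
                f"nonpositive radius at slice z={z_all[bad[0]]:.3f} A: "
                "the pathway is blocked")
    z, a, b, dz = _profile_geometry(profile)
    if len(z) < 2:
        raise ValueError("need at least 2 finite slices")
    if params is None:
        kappa = np.full(len(z), bulk.kappa_bulk)
    else:
        kappa = conductivity_model(a, b, params, bulk)
    contrib = (dz * A_TO_M) / (kappa * np.pi * a * b * A_TO_M ** 2)
    R = float(contrib.sum())
    from ellipore.ellipsoid import EllipsoidProfile

    shape = "ellipsoidal" if isinstance(profile, EllipsoidProfile) else "spherical"
    variant = f"{shape}-{'bulk' if params is None else 'model'}"
    return ConductanceEstimate(R=R, g=S_TO_PS / R, contributions=contrib,
                               variant=variant)


def resistance_table(profile, bulk: BulkConductivity,
                     params: ConductivityParams | None = None):
    """Per-slice decomposition (z, dz, a, b, kappa_ratio, R_slice) DataFrame."""
    import pandas as pd

    z, a, b, dz = _profile_geometry(profile)
    est = channel_resistance(profile, bulk, params)
    kappa = (np.full(len(z), bulk.kappa_bulk) if params is None
             else conductivity_model(a, b, params, bulk))
    return pd.DataFrame({"z": z, "dz": dz, "a": a, "b": b,
                         "kappa_ratio": kappa / bulk.kappa_bulk,
                         "R_slice": est.contributions})


_MULTISTART = [(c1, c2) for c1 in (0.5, 1.0, 2.0) for c2 in (2.0, 4.0, 8.0)]


def fit_conductivity(records, bulk: BulkConductivity) -> ConductivityParams:
    """Least-squares fit of (c1, c2) to observed per-record conductivities.

    Minimizes sum_i (kappa_model(a_i, b_i) - kappa_obs_i)^2 by Nelder-Mead
    from a fixed multistart grid; reports the SSE and the R^2 between
    predicted and observed conductances.
    """
    records = list(records)
    if len(records) < 2 or len({(r.a, r.b) for r in records}) < 2:
        raise ValueError("need >= 2 training records with distinct (a, b)")
    a = np.array([r.a for r in records])
    b = np.array([r.b for r in records])
    L = np.array([r.L for r in records])
    g_obs = np.array([r.g_MD for r in records])
    k_obs = np.array([r.kappa_obs for r in records])
    if np.allclose(k_obs, k_obs[0]) and np.allclose(a, a[0]) \
            and np.allclose(b, b[0]):
        raise ValueError("all training records identical: singular fit")

    def sse(p):
        c1, c2 = p
        k = expit(a * c1 - c2) * expit(b * c1 - c2) * bulk.kappa_bulk
        return float(np.sum((k - k_obs) ** 2))

    best = None
    for p0 in _MULTISTART:
        res = minimize(sse, np.array(p0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-18,
                                "maxiter": 4000, "maxfev": 4000})
        if best is None or res.fun < best.fun:
            best = res
    c1, c2 = best.x
    k_pred = expit(a * c1 - c2) * expit(b * c1 - c2) * bulk.kappa_bulk
    g_pred = k_pred * np.pi * a * b * A_TO_M ** 2 / (L * A_TO_M) * S_TO_PS
    ss_res = np.sum((g_obs - g_pred) ** 2)
    ss_tot = np.sum((g_obs - g_obs.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ConductivityParams(c1=float(c1), c2=float(c2),
                              residual=float(best.fun), r_squared=float(r2))


def read_training_csv(path) -> list[TrainingRecord]:
    """Load records from CSV with header a_angstrom, b_angstrom, L_angstrom, g_pS."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["a_angstrom", "b_angstrom", "L_angstrom", "g_pS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"training CSV missing column(s): {', '.join(missing)}")
    return [TrainingRecord(a=r.a_angstrom, b=r.b_angstrom, L=r.L_angstrom,
                           g_MD=r.g_pS) for r in df.itertuples()]
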