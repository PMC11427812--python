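"""Structure input, van der Waals radius assignment and z-axis alignment.

Pore profiling treats every atom as a hard van der Waals sphere, so all a
structure contributes downstream is coordinates, radii and masses.  The
:class:`AtomSet` container holds exactly that, and the operations here get a
PDB file into the canonical frame the probe algorithms assume: pore axis on
z, center of mass at the origin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

#: HOLE-like van der Waals radii (A).  The classic probe-profiling radius
#: set; user-overridable via :class:`RadiusTable`.
DEFAULT_RADII = {
    "C": 1.85,
    "O": 1.65,
    "N": 1.75,
    "S": 2.00,
    "P": 2.10,
    "H": 1.00,
}
DEFAULT_FALLBACK_RADIUS = 2.00

#: Residue names excluded by default: the pore wall is the protein or
#: nanotube, not crystallographic solvent/ions.
SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "SOL", "TIP", "TIP3", "TIP4", "SPC",
     "NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-", "K+"}
)

# Rough atomic masses (Da) for principal-axis weighting; exact isotope
# averages are irrelevant at the precision alignment needs.
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "SE": 78.971,
}
_DEFAULT_MASS = 12.011


@dataclass
class AtomSet:
    """Coordinates plus per-atom van der Waals radii of one structure.

    Parameters
    ----------
    positions : (N, 3) float array, A
    radii : (N,) float array, A
    elements : (N,) str array
    names : (N,) str array
        Atom names (e.g. ``CA``, ``OD1``).
    resnames : (N,) str array
    masses : (N,) float array, Da
    """

    positions: np.ndarray
    radii: np.ndarray
    elements: np.ndarray
    names: np.ndarray = None
    resnames: np.ndarray = None
    masses: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        self.elements = np.asarray(self.elements, dtype=object).reshape(n)
        if self.names is None:
            self.names = self.elements.copy()
        if self.resnames is None:
            self.resnames = np.full(n, "UNK", dtype=object)
        if self.masses is None:
            self.masses = np.array(
                [_MASSES.get(str(e).upper(), _DEFAULT_MASS) for e in self.elements]
            )
        self.names = np.asarray(self.names, dtype=object).reshape(n)
        self.resnames = np.asarray(self.resnames, dtype=object).reshape(n)
        self.masses = np.asarray(self.masses, dtype=float).reshape(n)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in AtomSet")
        if np.any(self.radii <= 0):
            raise ValueError("all van der Waals radii must be > 0")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def center_of_mass(self) -> np.ndarray:
        w = self.masses / self.masses.sum()
        return w @ self.positions

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        """Return a copy with positions mapped to ``R @ (x + t)``."""
        pos = (np.asarray(self.positions) + translation) @ np.asarray(rotation).T
        return replace(self, positions=pos)


@dataclass
class RadiusTable:
    """Element/atom-name pattern -> van der Waals radius (A); total lookup.

    ``rules`` maps either an element symbol (``"C"``) or an atom-name
    pattern (``"name:CA"``) to a radius.  Name rules take precedence over
    element rules; anything unmatched falls back to ``default_radius``.
    """

    rules: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    default_radius: float = DEFAULT_FALLBACK_RADIUS

    def __post_init__(self):
        if self.default_radius <= 0:
            raise ValueError("default_radius must be > 0")
        for k, v in self.rules.items():
            if v <= 0:
                raise ValueError(f"radius for {k!r} must be > 0, got {v}")

    def lookup(self, element: str, name: str = "") -> tuple[float, bool]:
        """Return ``(radius, matched)``; ``matched`` False means fallback."""
        key = f"name:{str(name).upper()}"
        if key in self.rules:
            return self.rules[key], True
        el = str(element).upper().capitalize()
        for cand in (str(element).upper(), el):
            if cand in self.rules:
                return self.rules[cand], True
        return self.default_radius, False

    @classmethod
    def from_yaml(cls, path) -> "RadiusTable":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        rules = dict(DEFAULT_RADII)
        rules.update({str(k): float(v) for k, v in data.get("radii", {}).items()})
        return cls(rules=rules,
                   default_radius=float(data.get("default_radius",
                                                 DEFAULT_FALLBACK_RADIUS)))


@dataclass
class AlignmentTransform:
    """Rigid transform ``x -> rotation @ (x + translation)``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        rtr = self.rotation @ self.rotation.T
        if not np.allclose(rtr, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1")

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return (np.asarray(positions) + self.translation) @ self.rotation.T

    def invert(self, positions: np.ndarray) -> np.ndarray:
        return np.asarray(positions) @ self.rotation - self.translation

    @classmethod
    def identity(cls) -> "AlignmentTransform":
        return cls(np.eye(3), np.zeros(3))


def read_structure(path, *, include_hydrogens: bool = True,
                   include_hetero: bool = True,
                   include_solvent: bool = False) -> AtomSet:
    """Read a PDB file into an :class:`AtomSet`.

    Alt-locs other than blank or 'A' are dropped; waters and free ions are
    excluded unless ``include_solvent``.  Elements are taken from the PDB
    element column when present, otherwise inferred from the atom name.
    Radii are *not* assigned here — call :func:`assign_radii`.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except (OSError, ValueError, EOFError) as exc:
            raise IOError(f"cannot read structure file {path!r}: {exc}") from exc

        atoms = u.atoms
        if hasattr(atoms, "altLocs"):
            keep = np.isin(atoms.altLocs, ("", " ", "A"))
            atoms = atoms[keep]
        if hasattr(atoms, "record_types") and not include_hetero:
            atoms = atoms[atoms.record_types == "ATOM"]

        names = atoms.names.astype(object)
        resnames = atoms.resnames.astype(object)
        elements = _elements_of(atoms, names)

    mask = np.ones(len(names), dtype=bool)
    if not include_solvent:
        mask &= ~np.isin(np.char.upper(resnames.astype(str)),
                         list(SOLVENT_RESNAMES))
    if not include_hydrogens:
        mask &= np.array([e.upper() != "H" for e in elements])

    if mask.sum() == 0:
        raise ValueError(f"no atoms left after filtering in {path!r}")

    elements = elements[mask]
    masses = np.array([_MASSES.get(e.upper(), _DEFAULT_MASS) for e in elements])
    return AtomSet(
        positions=atoms.positions[mask].astype(float),
        radii=np.full(mask.sum(), DEFAULT_FALLBACK_RADIUS),
        elements=elements,
        names=names[mask],
        resnames=resnames[mask],
        masses=masses,
    )


def _elements_of(atoms, names) -> np.ndarray:
    try:
        els = atoms.elements.astype(object)
        if all(str(e).strip() for e in els):
            return np.array([str(e).strip().capitalize() for e in els],
                            dtype=object)
    except Exception:
        pass
    # fall back to atom-name parsing: strip digits, try two-letter symbol
    out = []
    for nm in names:
        s = str(nm).strip().lstrip("0123456789")
        two = s[:2].upper()
        if two in _MASSES and two not in ("CA", "CL", "NA", "K"):
            out.append(two.capitalize())
        else:
            out.append(s[:1].upper())
    return np.array(out, dtype=object)


def assign_radii(atoms: AtomSet, table: RadiusTable | None = None) -> AtomSet:
    """Return a copy of ``atoms`` with van der Waals radii from ``table``.

    Total function: atoms matching no rule get ``table.default_radius``
    and a warning is logged once per unknown element.
    """
    table = table or RadiusTable()
    radii = np.empty(len(atoms))
    unmatched = set()
    for i, (el, nm) in enumerate(zip(atoms.elements, atoms.names)):
        radii[i], matched = table.lookup(el, nm)
        if not matched:
            unmatched.add(str(el))
    for el in sorted(unmatched):
        log.warning("no radius rule for element %r; using default %.2f A",
                    el, table.default_radius)
    return replace(atoms, radii=radii)


def gyration_tensor(atoms: AtomSet) -> np.ndarray:
    """Mass-weighted gyration tensor about the center of mass (A^2)."""
    x = atoms.positions - atoms.center_of_mass
    w = atoms.masses / atoms.masses.sum()
    return (w[:, None] * x).T @ x


def align_principal_axis(atoms: AtomSet) -> tuple[AtomSet, AlignmentTransform]:
    """Rotate so the longest principal axis lies on +z, center of mass at 0.

    The principal axis is the eigenvector of the mass-weighted gyration
    tensor with the largest eigenvalue.  Orientation is fixed
    deterministically: the axis points from lower to higher atom index
    (mass-weighted index trend), falling back to the +z hemisphere for
    index-symmetric structures.
    """
    if len(atoms) < 3:
        raise ValueError("need at least 3 atoms to define a principal axis")
    com = atoms.center_of_mass
    T = gyration_tensor(atoms)
    evals, evecs = np.linalg.eigh(T)  # ascending
    order = np.argsort(evals)[::-1]
    v1, v2, v3 = (evecs[:, i] for i in order)

    # sign of the pore axis: follow the atom-index trend along v1
    proj = (atoms.positions - com) @ v1
    idx = np.arange(len(atoms)) - (len(atoms) - 1) / 2.0
    trend = float(np.dot(idx, proj))
    if abs(trend) > 1e-9:
        if trend < 0:
            v1 = -v1
    elif v1[2] < 0:
        v1 = -v1
    # deterministic secondary axes: largest-|component| positive
    v2 = v2 if v2[np.argmax(np.abs(v2))] > 0 else -v2
    v3 = np.cross(v1, v2)
    v3 /= np.linalg.norm(v3)
    v2 = np.cross(v3, v1)

    rotation = np.stack([v2, v3, v1])  # rows: new x, y, z axes
    if np.linalg.det(rotation) < 0:  # defensive; cross products fix this
        rotation[1] = -rotation[1]
    tf = AlignmentTransform(rotation=rotation, translation=-com)
    return atoms.transformed(rotation, -com), tf
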