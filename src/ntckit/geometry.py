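"""Rigid-geometry primitives for dinucleotide-step analysis.

Torsion angles follow the IUPAC/crystallographic convention: the cis
(eclipsed) arrangement is 0 degrees, values lie in (-180, 180], and the sign
is given by the right-hand rule looking down the central bond.  All
coordinates are in angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "StepParameters",
    "PARAMETER_NAMES",
    "TORSION_NAMES",
    "DISTANCE_NAMES",
    "wrap_angle",
    "dihedral",
    "circular_difference",
    "signed_circular_difference",
    "superpose_rmsd",
    "SuperposeResult",
    "compute_step_parameters",
    "UndefinedTorsionError",
    "DegenerateGeometryError",
]

#: cross-product norm below this fraction of the bond-length scale counts as collinear
COLLINEAR_TOL = 1e-8

TORSION_NAMES = (
    "delta1", "epsilon1", "zeta1", "alpha2", "beta2", "gamma2", "delta2",
    "chi1", "chi2", "mu",
)
DISTANCE_NAMES = ("dist_NN", "dist_CC")
PARAMETER_NAMES = TORSION_NAMES + DISTANCE_NAMES

#: boolean mask over the 12 parameters: True where the dimension is angular
CIRCULAR_MASK = np.array([True] * 10 + [False, False])


class UndefinedTorsionError(ValueError):
    """Raised when three consecutive torsion atoms are collinear."""


class DegenerateGeometryError(ValueError):
    """Raised for point sets that do not define a rigid superposition."""


def wrap_angle(angle):
    """Wrap an angle (degrees) into the interval (-180, 180]."""
    return -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Cis is 0; the sign follows the right-hand convention looking from p2
    towards p3.  Raises :class:`UndefinedTorsionError` when p1,p2,p3 or
    p2,p3,p4 are collinear (the torsion is then geometrically undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(np.linalg.norm(b1) * np.linalg.norm(b2),
                np.linalg.norm(b2) * np.linalg.norm(b3), 1e-300)
    if np.linalg.norm(n1) <= COLLINEAR_TOL * scale or \
       np.linalg.norm(n2) <= COLLINEAR_TOL * scale:
        raise UndefinedTorsionError("collinear atoms: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2n), n2))
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def circular_difference(a, b):
    """Unsigned angular separation of a and b (degrees), in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def signed_circular_difference(a, b):
    """Signed angular displacement a - b wrapped to (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class SuperposeResult:
    """Optimal proper-rotation rigid superposition of Y onto X."""

    rmsd: float
    rotation: np.ndarray    # 3x3, det +1
    translation: np.ndarray  # 3-vector

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to an (n, 3) array."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def superpose_rmsd(X, Y) -> SuperposeResult:
    """Least-squares rigid superposition of point set Y onto X.

    Only proper rotations are allowed (determinant +1), so a mirror image of
    X does not superpose onto X with zero r.m.s.d.  Points must correspond
    row by row.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise DegenerateGeometryError(
            f"point sets must be matching (n, 3) arrays, got {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometryError("at least 3 points are required")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    Xc = X - cx
    Yc = Y - cy
    # collinear/degenerate sets do not pin down a unique rotation
    for M in (Xc, Yc):
        s = np.linalg.svd(M, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(Xc, Yc)
    R = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(n)
    translation = cx - R @ cy
    return SuperposeResult(rmsd=rmsd, rotation=R, translation=translation)


@dataclass(frozen=True)
class StepParameters:
    """The 12-dimensional descriptor of one dinucleotide step.

    Nine bonded torsions (seven sugar-phosphate backbone torsions delta1,
    epsilon1, zeta1, alpha2, beta2, gamma2, delta2 plus the two glycosidic
    torsions chi1, chi2), the base-orientation pseudo-torsion mu
    (N1/9(1)-C1'(1)-C1'(2)-N1/9(2)) and two distances: N1/9(1)-N1/9(2) and
    C1'(1)-C1'(2).  Torsions in degrees in (-180, 180], distances in
    angstroms.
    """

    delta1: float
    epsilon1: float
    zeta1: float
    alpha2: float
    beta2: float
    gamma2: float
    delta2: float
    chi1: float
    chi2: float
    mu: float
    dist_NN: float
    dist_CC: float

    def __post_init__(self):
        for name in TORSION_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not (-180.0 < v <= 180.0 + 1e-9):
                raise ValueError(f"{name}={v!r} outside (-180, 180]")
        for name in DISTANCE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name}={v!r} must be a positive distance")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "StepParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (12,):
            raise ValueError(f"expected 12 parameters, got shape {values.shape}")
        wrapped = values.copy()
        wrapped[:10] = wrap_angle(wrapped[:10])
        return cls(**dict(zip(PARAMETER_NAMES, wrapped)))

    def __iter__(self):
        return iter(self.as_array())


# atom quadruples defining each torsion; entries are (residue_index, role)
TORSION_ATOMS = {
    "delta1": ((1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")),
    "epsilon1": ((1, "C4'"), (1, "C3'"), (1, "O3'"), (2, "P")),
    "zeta1": ((1, "C3'"), (1, "O3'"), (2, "P"), (2, "O5'")),
    "alpha2": ((1, "O3'"), (2, "P"), (2, "O5'"), (2, "C5'")),
    "beta2": ((2, "P"), (2, "O5'"), (2, "C5'"), (2, "C4'")),
    "gamma2": ((2, "O5'"), (2, "C5'"), (2, "C4'"), (2, "C3'")),
    "delta2": ((2, "C5'"), (2, "C4'"), (2, "C3'"), (2, "O3'")),
    "chi1": ((1, "O4'"), (1, "C1'"), (1, "N"), (1, "C")),
    "chi2": ((2, "O4'"), (2, "C1'"), (2, "N"), (2, "C")),
    "mu": ((1, "N"), (1, "C1'"), (2, "C1'"), (2, "N")),
}

DISTANCE_ATOMS = {
    "dist_NN": ((1, "N"), (2, "N")),
    "dist_CC": ((1, "C1'"), (2, "C1'")),
}


def compute_step_parameters(step) -> StepParameters:
    """Measure the 12 step parameters from a :class:`DinucleotideStep`.

    ``step`` must expose ``coord((residue_index, role))`` returning a
    3-vector for each of the 18 canonical atom roles.
    """
    values = {}
    for name, quad in TORSION_ATOMS.items():
        values[name] = dihedral(*(step.coord(r) for r in quad))
    for name, (a, b) in DISTANCE_ATOMS.items():
        values[name] = float(np.linalg.norm(step.coord(a) - step.coord(b)))
    return StepParameters(**values)
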