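"""Synthetic dinucleotide construction and synthetic reference sets.

The builder places the 18 canonical step atoms by sequential internal-
coordinate (NeRF-style) construction: each atom is positioned from a parent
triple by an idealized bond length, an idealized bond angle and a torsion.
The seven backbone torsions, the two glycosidic torsions and the pseudo-
torsion mu are prescribed exactly, so measuring the built step recovers them
to numerical precision; the N-N and C1'-C1' distances are emergent.

mu is not a bonded torsion, so it is imposed by solving for the torsional
placement of the second base nitrogen on its chemically constrained circle
(fixed C1'-N bond length and N-C1'-O4' angle).  Depending on the backbone
geometry only an arc of mu values may be attainable; prescribing a value
outside that arc raises :class:`BuildError`.

The synthetic reference generator emulates the schema of a real conformer
table (per-class means, e.s.d. values and representative coordinates) with a
handful of well-separated classes, so the classifier, scoring and reporting
machinery can be exercised without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import (
    PARAMETER_NAMES,
    TORSION_NAMES,
    StepParameters,
    circular_difference,
    compute_step_parameters,
    dihedral,
    signed_circular_difference,
    superpose_rmsd,
    wrap_angle,
)
from .structure_io import ATOM_ROLES, AtomRecord, DinucleotideStep, ResidueRef

__all__ = [
    "InternalGeometry",
    "DEFAULT_GEOMETRY",
    "SyntheticSpec",
    "BuildError",
    "build_dinucleotide",
    "attainable_mu_range",
    "sample_step_parameters",
    "generate_reference",
    "build_polymer",
    "step_to_structure",
    "residues_to_structure",
]


class BuildError(ValueError):
    """Requested parameters cannot be realized geometrically."""


@dataclass(frozen=True)
class InternalGeometry:
    """Idealized bond lengths (A) and angles (deg) for the 18-atom chain.

    Values are standard nucleotide stereochemistry; they are constants of the
    generator, not fitted quantities, and may be overridden wholesale.
    """

    bonds: dict = field(default_factory=lambda: {
        ("C5'", "C4'"): 1.510,
        ("C4'", "C3'"): 1.524,
        ("C3'", "O3'"): 1.423,
        ("O3'", "P"): 1.607,
        ("P", "O5'"): 1.593,
        ("O5'", "C5'"): 1.440,
        ("C4'", "O4'"): 1.453,
        ("O4'", "C1'"): 1.414,
        ("C1'", "N"): 1.470,
        ("N", "C"): 1.370,
    })
    angles: dict = field(default_factory=lambda: {
        ("C5'", "C4'", "C3'"): 115.5,
        ("C4'", "C3'", "O3'"): 110.7,
        ("C3'", "O3'", "P"): 119.7,
        ("O3'", "P", "O5'"): 104.0,
        ("P", "O5'", "C5'"): 120.9,
        ("O5'", "C5'", "C4'"): 111.5,
        ("C3'", "C4'", "O4'"): 105.6,
        ("C4'", "O4'", "C1'"): 109.7,
        ("O4'", "C1'", "N"): 108.2,
        ("C1'", "N", "C"): 126.4,
    })
    # fixed placement torsions for atoms whose torsion is not a step parameter
    torsion_O4: float = -121.0   # O4'-C4'-C3'-O3'
    torsion_C1: float = 25.0     # C1'-O4'-C4'-C3'
    torsion_N: float = -120.0    # N-C1'-O4'-C4'

    def __post_init__(self):
        for pair, b in self.bonds.items():
            if not (1.2 < b < 1.8):
                raise ValueError(f"bond {pair}: {b} A outside (1.2, 1.8)")
        for triple, a in self.angles.items():
            if not (90.0 < a < 135.0):
                raise ValueError(f"angle {triple}: {a} deg outside (90, 135)")


DEFAULT_GEOMETRY = InternalGeometry()


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise BuildError("degenerate placement: zero-length bond vector")
    return v / n


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |d-c| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = _unit(c - b)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise BuildError("degenerate placement: collinear parent triple")
    n = n / nn
    m = np.cross(n, bc)
    return c + bond * (-np.cos(theta) * bc
                       + np.sin(theta) * (np.cos(phi) * m - np.sin(phi) * n))


def _torsions_dict(params) -> dict:
    if isinstance(params, StepParameters):
        d = {name: getattr(params, name) for name in TORSION_NAMES}
    else:
        d = dict(params)
    missing = [n for n in TORSION_NAMES if n != "mu" and n not in d]
    if missing:
        raise ValueError(f"missing torsions: {missing}")
    return d


def _build_partial(t: dict, geom: InternalGeometry) -> dict:
    """Everything except the second base (N and C2/4 of residue 2)."""
    b, ang = geom.bonds, geom.angles
    c: dict = {}
    # seed triple for residue 1
    c[(1, "C5'")] = np.zeros(3)
    c[(1, "C4'")] = np.array([b[("C5'", "C4'")], 0.0, 0.0])
    th = np.radians(180.0 - ang[("C5'", "C4'", "C3'")])
    c[(1, "C3'")] = c[(1, "C4'")] + b[("C4'", "C3'")] * np.array([np.cos(th), np.sin(th), 0.0])
    # the seven-torsion backbone chain
    chain = [
        ((1, "O3'"), (1, "C5'"), (1, "C4'"), (1, "C3'"),
         b[("C3'", "O3'")], ang[("C4'", "C3'", "O3'")], t["delta1"]),
        ((2, "P"), (1, "C4'"), (1, "C3'"), (1, "O3'"),
         b[("O3'", "P")], ang[("C3'", "O3'", "P")], t["epsilon1"]),
        ((2, "O5'"), (1, "C3'"), (1, "O3'"), (2, "P"),
         b[("P", "O5'")], ang[("O3'", "P", "O5'")], t["zeta1"]),
        ((2, "C5'"), (1, "O3'"), (2, "P"), (2, "O5'"),
         b[("O5'", "C5'")], ang[("P", "O5'", "C5'")], t["alpha2"]),
        ((2, "C4'"), (2, "P"), (2, "O5'"), (2, "C5'"),
         b[("C5'", "C4'")], ang[("O5'", "C5'", "C4'")], t["beta2"]),
        ((2, "C3'"), (2, "O5'"), (2, "C5'"), (2, "C4'"),
         b[("C4'", "C3'")], ang[("C5'", "C4'", "C3'")], t["gamma2"]),
        ((2, "O3'"), (2, "C5'"), (2, "C4'"), (2, "C3'"),
         b[("C3'", "O3'")], ang[("C4'", "C3'", "O3'")], t["delta2"]),
    ]
    for role, a1, a2, a3, bond, angle, torsion in chain:
        c[role] = place_atom(c[a1], c[a2], c[a3], bond, angle, torsion)
    # sugar rings (identical rules for both residues)
    for i in (1, 2):
        c[(i, "O4'")] = place_atom(c[(i, "O3'")], c[(i, "C3'")], c[(i, "C4'")],
                                   b[("C4'", "O4'")], ang[("C3'", "C4'", "O4'")],
                                   geom.torsion_O4)
        c[(i, "C1'")] = place_atom(c[(i, "C3'")], c[(i, "C4'")], c[(i, "O4'")],
                                   b[("O4'", "C1'")], ang[("C4'", "O4'", "C1'")],
                                   geom.torsion_C1)
    # first base attachment
    c[(1, "N")] = place_atom(c[(1, "C4'")], c[(1, "O4'")], c[(1, "C1'")],
                             b[("C1'", "N")], ang[("O4'", "C1'", "N")],
                             geom.torsion_N)
    c[(1, "C")] = place_atom(c[(1, "O4'")], c[(1, "C1'")], c[(1, "N")],
                             b[("N", "C")], ang[("C1'", "N", "C")], t["chi1"])
    return c


def _n2_position(c: dict, torsion: float, geom: InternalGeometry) -> np.ndarray:
    return place_atom(c[(2, "C4'")], c[(2, "O4'")], c[(2, "C1'")],
                      geom.bonds[("C1'", "N")], geom.angles[("O4'", "C1'", "N")],
                      torsion)


def _mu_of(c: dict, n2: np.ndarray) -> float:
    return dihedral(c[(1, "N")], c[(1, "C1'")], c[(2, "C1'")], n2)


_GRID = np.linspace(-180.0, 180.0, 361)


def _mu_curve(c: dict, geom: InternalGeometry) -> np.ndarray:
    """Measured mu for every grid value of the N(2) placement torsion (vectorized)."""
    a, b2, c2 = c[(2, "C4'")], c[(2, "O4'")], c[(2, "C1'")]
    bond = geom.bonds[("C1'", "N")]
    theta = np.radians(geom.angles[("O4'", "C1'", "N")])
    phi = np.radians(_GRID)
    bc = _unit(c2 - b2)
    n = _unit(np.cross(b2 - a, bc))
    m = np.cross(n, bc)
    n2 = (c2 + bond * (-np.cos(theta) * bc)
          + bond * np.sin(theta) * (np.cos(phi)[:, None] * m - np.sin(phi)[:, None] * n))
    # dihedral N(1)-C1'(1)-C1'(2)-N(2) for all candidate N(2) positions
    p1, p2, p3 = c[(1, "N")], c[(1, "C1'")], c[(2, "C1'")]
    b1 = p2 - p1
    bm = p3 - p2
    b3 = n2 - p3
    n1 = np.cross(b1, bm)
    nn2 = np.cross(bm[None, :], b3)
    bmn = bm / np.linalg.norm(bm)
    x = nn2 @ n1
    y = nn2 @ np.cross(n1, bmn)
    return np.degrees(np.arctan2(y, x))


def _solve_n2_torsion(c: dict, mu: float, geom: InternalGeometry) -> float:
    """Torsion t for the second base nitrogen such that the measured mu hits target."""
    f = _mu_curve(c, geom)
    g = signed_circular_difference(f, mu)
    roots = []
    for i in range(len(_GRID) - 1):
        g1, g2 = g[i], g[i + 1]
        if abs(g1) < 1e-12:
            roots.append(_GRID[i])
            continue
        if g1 * g2 < 0 and abs(g1 - g2) < 180.0:  # genuine crossing, not a branch jump
            t0, t1 = _GRID[i], _GRID[i + 1]
            root = brentq(
                lambda t: float(signed_circular_difference(_mu_of(c, _n2_position(c, t, geom)), mu)),
                t0, t1, xtol=1e-12)
            roots.append(root)
    if abs(g[-1]) < 1e-12:
        roots.append(_GRID[-1])
    if not roots:
        lo, hi = attainable_mu_range(c, geom)
        raise BuildError(
            f"mu = {mu:.2f} deg is not attainable for this backbone "
            f"(attainable arc approximately [{lo:.2f}, {hi:.2f}] deg)")
    # deterministic choice: the solution nearest the natural placement torsion
    roots.sort()
    return min(roots, key=lambda t: (float(circular_difference(t, geom.torsion_N)), t))


def attainable_mu_range(c_or_torsions, geom: InternalGeometry = DEFAULT_GEOMETRY):
    """Approximate attainable (mu_min, mu_max) arc in degrees for a backbone.

    Accepts either the partial coordinate dict or a torsion mapping.  When the
    full circle is attainable, returns (-180.0, 180.0).
    """
    c = c_or_torsions if isinstance(c_or_torsions, dict) and (1, "C1'") in c_or_torsions \
        else _build_partial(_torsions_dict(c_or_torsions), geom)
    f = _mu_curve(c, geom)
    u = np.unwrap(np.radians(f))
    lo, hi = np.degrees(u.min()), np.degrees(u.max())
    if hi - lo >= 360.0:
        return (-180.0, 180.0)
    return (lo, hi)


_RES_NAME = "DA"
_ATOM_NAMES = {"N": "N9", "C": "C4"}  # synthetic bases are purine-like


def _make_step(coords: dict, chain_id: str = "A", seq1: int = 1,
               name: str = "") -> DinucleotideStep:
    atoms = {}
    for idx, role in ATOM_ROLES:
        atoms[(idx, role)] = AtomRecord(
            name=_ATOM_NAMES.get(role, role),
            element=role[0] if role not in ("N", "C") else _ATOM_NAMES[role][0],
            xyz=np.asarray(coords[(idx, role)], dtype=float),
        )
    first = ResidueRef(1, chain_id, _RES_NAME, seq1)
    second = ResidueRef(1, chain_id, _RES_NAME, seq1 + 1)
    step = DinucleotideStep(first=first, second=second, atoms=atoms)
    step.step_name = name or f"synt_{chain_id}_{_RES_NAME}{seq1}_{_RES_NAME}{seq1 + 1}"
    return step


def build_dinucleotide(params, geom: InternalGeometry = DEFAULT_GEOMETRY) -> DinucleotideStep:
    """Build an 18-atom step realizing the prescribed torsions exactly.

    ``params`` is a :class:`StepParameters` or a mapping with the nine bonded
    torsions; ``mu`` may be given (imposed by construction) or omitted/None,
    in which case the second base nitrogen takes the same idealized placement
    as the first and mu is emergent.  The two distances are always emergent.
    The build is deterministic.
    """
    t = _torsions_dict(params)
    c = _build_partial(t, geom)
    mu = t.get("mu")
    if mu is None:
        n2_torsion = geom.torsion_N
    else:
        n2_torsion = _solve_n2_torsion(c, float(mu), geom)
    c[(2, "N")] = _n2_position(c, n2_torsion, geom)
    c[(2, "C")] = place_atom(c[(2, "O4'")], c[(2, "C1'")], c[(2, "N")],
                             geom.bonds[("N", "C")], geom.angles[("C1'", "N", "C")],
                             t["chi2"])
    return _make_step(c)


# ---------------------------------------------------------------------------
# random parameter sampling

# realistic-looking sampling bands are unnecessary: bond angles are fixed, so
# any torsion combination yields a valid (if strained) chain; mu alone is
# constrained and is sampled inside its attainable arc.
def sample_step_parameters(rng: np.random.Generator,
                           geom: InternalGeometry = DEFAULT_GEOMETRY,
                           mu_margin: float = 1.0) -> StepParameters:
    """Draw a random, geometrically realizable parameter set (seeded)."""
    t = {name: float(rng.uniform(-180.0, 180.0))
         for name in TORSION_NAMES if name != "mu"}
    c = _build_partial(t, geom)
    lo, hi = attainable_mu_range(c, geom)
    if hi - lo >= 360.0:
        mu = float(rng.uniform(-180.0, 180.0))
    else:
        span = hi - lo
        margin = min(mu_margin, 0.25 * span)
        mu = float(wrap_angle(rng.uniform(lo + margin, hi - margin)))
    t["mu"] = mu
    step = build_dinucleotide(t, geom)
    return compute_step_parameters(step)


# ---------------------------------------------------------------------------
# synthetic reference sets

_BASE_TORSIONS = {
    "delta1": 84.0, "epsilon1": -170.0, "zeta1": -95.0,
    "alpha2": -62.0, "beta2": 175.0, "gamma2": 55.0, "delta2": 84.0,
    "chi1": -98.0, "chi2": -98.0,
}

# per-class offsets on (epsilon1, zeta1, alpha2, beta2, gamma2); the shared
# delta/chi values keep every class chain-compatible with every other
_CLASS_OFFSETS = [
    (0.0, 0.0, 0.0, 0.0, 0.0),
    (0.0, 110.0, 95.0, 0.0, 0.0),
    (95.0, -120.0, 0.0, -110.0, 0.0),
    (0.0, 0.0, -120.0, 100.0, 95.0),
    (-110.0, 95.0, 0.0, 0.0, -120.0),
    (110.0, 0.0, 110.0, 0.0, 110.0),
    (0.0, -110.0, 0.0, 120.0, -100.0),
    (120.0, 120.0, -95.0, -60.0, 60.0),
]

_NTC_PREFIXES = ["AA", "BB", "ZZ", "OP", "IC", "AB", "BA", "SS"]
_CANA_SYMBOLS = ["AAA", "BBB", "ZZZ", "OPN", "ICL", "ABW", "BAW", "SYN"]

_DEFAULT_ESD = np.array([8.0] * 7 + [8.0, 8.0, 10.0, 0.30, 0.25])


@dataclass
class SyntheticSpec:
    """Conditions for a synthetic reference set.

    Class means are pairwise separated by more than 3x the pooled e.s.d. in
    scaled parameter distance, so the classes are distinguishable by
    construction; violating specs are rejected.
    """

    n_classes: int = 3
    samples_per_class: int = 50
    seed: int = 0
    esd: np.ndarray | None = None

    def __post_init__(self):
        if not (1 <= self.n_classes <= len(_CLASS_OFFSETS)):
            raise ValueError(f"n_classes must be in [1, {len(_CLASS_OFFSETS)}]")
        if self.esd is None:
            self.esd = _DEFAULT_ESD.copy()
        self.esd = np.asarray(self.esd, dtype=float)
        if self.esd.shape != (12,) or np.any(self.esd <= 0):
            raise ValueError("esd must be 12 positive values")


def _class_torsions(j: int) -> dict:
    t = dict(_BASE_TORSIONS)
    off = _CLASS_OFFSETS[j]
    for name, o in zip(("epsilon1", "zeta1", "alpha2", "beta2", "gamma2"), off):
        t[name] = float(wrap_angle(t[name] + o))
    return t


def _scaled_distance(p, q, scaling):
    d = np.empty(12)
    d[:10] = circular_difference(p[:10], q[:10])
    d[10:] = np.abs(p[10:] - q[10:])
    return float(np.sqrt(np.sum((d / scaling) ** 2)))


def generate_reference(spec: SyntheticSpec, geom: InternalGeometry = DEFAULT_GEOMETRY):
    """Build a validated synthetic reference set plus labeled training vectors.

    Returns ``(refset, X, y)``: the reference set, an (n, 12) array of noisy
    parameter vectors (wrapped-normal noise on angular dimensions, truncated
    normal on distances, sigma = the class e.s.d.) and their class labels.
    Representatives are built at the class means; mu and the two distances
    are emergent from the probe build and become the class means for those
    parameters.
    """
    from .reference import NtCClass, ReferenceSet

    rng = np.random.default_rng(spec.seed)
    classes = []
    for j in range(spec.n_classes):
        t = _class_torsions(j)
        step = build_dinucleotide(t, geom)  # natural mu: both residues congruent
        measured = compute_step_parameters(step).as_array()
        code = f"{_NTC_PREFIXES[j]}{j + 1:02d}"
        classes.append(NtCClass(
            ntc=code,
            cana=_CANA_SYMBOLS[j],
            means=measured,
            esd=spec.esd.copy(),
            representative=step.coords(),
        ))
    refset = ReferenceSet(classes=classes, version=f"synthetic-{spec.seed}")

    pooled = refset.pooled_esd()
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            sep = _scaled_distance(classes[a].means, classes[b].means, pooled)
            if sep <= 3.0:
                raise ValueError(
                    f"classes {classes[a].ntc} and {classes[b].ntc} are inseparable "
                    f"(scaled distance {sep:.2f} <= 3)")

    X, y = [], []
    for cls in classes:
        for _ in range(spec.samples_per_class):
            v = cls.means + rng.normal(0.0, spec.esd)
            v[:10] = wrap_angle(v[:10])
            for k in (10, 11):
                while v[k] <= 0.05:  # truncate distances away from zero
                    v[k] = cls.means[k] + rng.normal(0.0, spec.esd[k])
            X.append(v)
            y.append(cls.ntc)
    return refset, np.array(X), np.array(y)


# ---------------------------------------------------------------------------
# polymers and structure serialization

_STEP_RES1_ROLES = [(1, r) for r in ("C5'", "C4'", "C3'", "O3'", "C1'", "O4'", "N", "C")]
_STEP_RES2_ROLES = [(2, r) for r in ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'", "O4'", "N", "C")]


def build_polymer(class_sequence, refset, chain_id: str = "A", tol: float = 1e-6):
    """Chain of n+1 residues whose n successive steps realize the named classes.

    Built by rigid concatenation of class representatives: each next
    representative is superposed so that its first-residue atoms coincide
    with the current terminal residue.  Consecutive classes must agree on
    the shared residue's internal geometry (delta and chi at least); a
    mismatch beyond ``tol`` raises :class:`BuildError`.

    Returns a gemmi structure with one chain.
    """
    if not class_sequence:
        raise ValueError("class_sequence must name at least one class")
    reps = []
    for code in class_sequence:
        cls = refset.get(code)
        reps.append(np.asarray(cls.representative, dtype=float))

    role_index = {role: i for i, role in enumerate(ATOM_ROLES)}
    res1_idx = [role_index[r] for r in _STEP_RES1_ROLES]
    res2_idx = [role_index[r] for r in _STEP_RES2_ROLES]

    def residue_atoms(rep, which):
        idx = res1_idx if which == 1 else res2_idx
        roles = _STEP_RES1_ROLES if which == 1 else _STEP_RES2_ROLES
        return {role[1]: rep[i] for role, i in zip(roles, idx)}

    residues = [residue_atoms(reps[0], 1), residue_atoms(reps[0], 2)]
    for code, rep in zip(class_sequence[1:], reps[1:]):
        last = residues[-1]
        target = np.array([last[r[1]] for r in _STEP_RES1_ROLES])
        mobile = rep[res1_idx]
        sup = superpose_rmsd(target, mobile)
        if sup.rmsd > tol:
            raise BuildError(
                f"class {code} cannot extend the chain: shared-residue geometry "
                f"mismatch (r.m.s.d. {sup.rmsd:.2e} A > {tol:.0e} A); consecutive "
                "classes must agree on the shared residue's delta/chi geometry")
        moved = sup.transform(rep)
        residues.append(residue_atoms(moved, 2))
    return residues_to_structure(residues, chain_id=chain_id, name="polymer")


def residues_to_structure(residues, chain_id: str = "A", name: str = "synt") -> "gemmi.Structure":
    """Assemble role->xyz residue dicts into a single-chain gemmi structure."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = name
    model = gemmi.Model(1)
    chain = gemmi.Chain(chain_id)
    for i, atoms in enumerate(residues, start=1):
        res = gemmi.Residue()
        res.name = _RES_NAME
        res.seqid = gemmi.SeqId(i, " ")
        for role, xyz in atoms.items():
            atom = gemmi.Atom()
            atom.name = _ATOM_NAMES.get(role, role)
            atom.element = gemmi.Element(_ATOM_NAMES.get(role, role)[0])
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    return structure


def step_to_structure(step: DinucleotideStep, name: str = "synt") -> "gemmi.Structure":
    """Serialize one built step as a 2-residue gemmi structure."""
    residues = []
    for idx, roles in ((1, _STEP_RES1_ROLES), (2, _STEP_RES2_ROLES)):
        residues.append({role[1]: step.atoms[role].xyz for role in roles})
    return residues_to_structure(residues, chain_id=step.first.chain_id, name=name)
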