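"""Reading coordinate files and detecting assignable dinucleotide steps.

A dinucleotide step is the pair of consecutive nucleotides of one chain,
described by 18 canonical atoms: C5', C4', C3', O3', C1', O4' and the two
base atoms N1/9 and C2/4 of the first residue, plus the same set together
with P and O5' of the second residue.  Only pairs in which all 18 atoms are
resolvable and the O3'(1)-P(2) linkage is within a covalent-bond cutoff form
a step; residues missing any required atom contribute no step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "DinucleotideStep",
    "ATOM_ROLES",
    "read_structure",
    "detect_steps",
    "step_name",
    "ParseError",
    "EmptyStructureError",
    "DEFAULT_LINKAGE_CUTOFF",
]

#: default O3'(1)-P(2) consecutiveness cutoff; a covalent O-P bond is ~1.6 A,
#: the generous margin tolerates poorly refined linkages
DEFAULT_LINKAGE_CUTOFF = 2.5

#: the 18 canonical atom roles of a step, in fixed order
ATOM_ROLES = (
    (1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'"),
    (1, "C1'"), (1, "O4'"), (1, "N"), (1, "C"),
    (2, "P"), (2, "O5'"),
    (2, "C5'"), (2, "C4'"), (2, "C3'"), (2, "O3'"),
    (2, "C1'"), (2, "O4'"), (2, "N"), (2, "C"),
)

_SUGAR_ROLES = ("C5'", "C4'", "C3'", "O3'", "C1'", "O4'")


class ParseError(ValueError):
    """Coordinate file could not be parsed under the requested standard."""


class EmptyStructureError(ValueError):
    """Parsed file contains no atomic coordinates."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    xyz: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "xyz", xyz)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class ResidueRef:
    """Author-numbered identity of one residue instance."""

    model_no: int
    chain_id: str
    res_name: str
    res_seq: int
    ins_code: str = ""
    altloc: str = ""

    def label(self) -> str:
        seg = self.res_name
        if self.altloc:
            seg += f".{self.altloc}"
        seg += str(self.res_seq)
        if self.ins_code:
            seg += f".{self.ins_code}"
        return seg


@dataclass
class DinucleotideStep:
    """Two consecutive nucleotides with the 18 canonical atoms resolved."""

    first: ResidueRef
    second: ResidueRef
    atoms: dict = field(default_factory=dict)  # (residue_index, role) -> AtomRecord
    step_name: str = ""

    def __post_init__(self):
        missing = [r for r in ATOM_ROLES if r not in self.atoms]
        if missing:
            raise ValueError(f"step is missing atom roles: {missing}")

    def coord(self, role) -> np.ndarray:
        return self.atoms[role].xyz

    def coords(self) -> np.ndarray:
        """All 18 atom positions as an (18, 3) array in canonical role order."""
        return np.array([self.atoms[r].xyz for r in ATOM_ROLES])


def read_structure(path, format: str = "auto") -> gemmi.Structure:
    """Read an mmCIF or PDB coordinate file into a gemmi structure.

    All models are retained, heteroatoms stay in place (gemmi flags them as
    HETATM), and author numbering is preserved.  ``format`` may be
    ``"mmcif"``, ``"pdb"`` or ``"auto"`` (detect from content/extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    structure.setup_entities()
    if sum(len(ch) for model in structure for ch in model) == 0:
        raise EmptyStructureError(f"{path}: no atomic coordinates found")
    if not structure.name:
        structure.name = path.stem
    return structure


def _blank(altloc: str) -> str:
    return "" if altloc in ("", "\x00", " ") else altloc


def _atom_map(residue: gemmi.Residue) -> dict:
    """name -> {altloc: gemmi.Atom}, hydrogens excluded."""
    out: dict = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        out.setdefault(atom.name, {})[_blank(atom.altloc)] = atom
    return out


def _base_atoms(atom_map) -> tuple | None:
    """Resolve the base-attachment atoms: (N9, C4) for purines, (N1, C2) otherwise."""
    if "N9" in atom_map and "C4" in atom_map:
        return "N9", "C4"
    if "N1" in atom_map and "C2" in atom_map:
        return "N1", "C2"
    return None


def _required_names(atom_map, with_phosphate: bool) -> dict | None:
    """role -> actual atom name, or None if the residue cannot serve."""
    base = _base_atoms(atom_map)
    if base is None:
        return None
    names = {role: role for role in _SUGAR_ROLES}
    names["N"], names["C"] = base
    if with_phosphate:
        names["P"], names["O5'"] = "P", "O5'"
    if any(n not in atom_map for n in names.values()):
        return None
    return names


def _resolve(atom_map, name: str, altloc: str, min_occupancy):
    """Pick the atom variant matching ``altloc``, with blank as fallback."""
    variants = atom_map.get(name, {})
    atom = variants.get(altloc, variants.get(""))
    if atom is None:
        return None
    if min_occupancy is not None and atom.occ < min_occupancy:
        return None
    return atom

def _record(atom) -> AtomRecord:
    return AtomRecord(
        name=atom.name,
        element=atom.element.name,
        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        altloc=_blank(atom.altloc),
        occupancy=min(max(float(atom.occ), 0.0), 1.0),
    )


def detect_steps(structure: gemmi.Structure, model_no: int = 1,
                 linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
                 min_occupancy: float | None = None,
                 pdb_id: str | None = None) -> list[DinucleotideStep]:
    """Detect assignable dinucleotide steps in one model.

    One step is produced for every pair of consecutive nucleotide residues of
    a chain whose O3'(1)-P(2) distance is within ``linkage_cutoff`` and whose
    18 canonical atoms all resolve.  Purine vs pyrimidine base atoms are
    chosen per residue by the presence of N9.  Alternate locations are
    expanded into separate steps, one per altloc id present among the
    required atoms (blank-altloc atoms serve as fallback for every id);
    conflicting combinations that cannot be resolved are skipped.  An empty
    list is a valid result.
    """
    model = None
    for m in structure:
        if m.num == model_no:
            model = m
            break
    if model is None:
        raise ValueError(f"model {model_no} not present in structure")
    multi_model = len(structure) > 1
    pid = (pdb_id or structure.name or "xxxx").lower()

    steps: list[DinucleotideStep] = []
    for chain in model:
        residues = [r for r in chain if not r.is_water()]
        for r1, r2 in zip(residues, residues[1:]):
            map1, map2 = _atom_map(r1), _atom_map(r2)
            names1 = _required_names(map1, with_phosphate=False)
            names2 = _required_names(map2, with_phosphate=True)
            if names1 is None or names2 is None:
                continue
            altlocs = sorted(
                {_blank(a) for name in names1.values() for a in map1.get(name, {})} |
                {_blank(a) for name in names2.values() for a in map2.get(name, {})} -
                {""}
            )
            altlocs = [a for a in altlocs if a] or [""]
            for alt in altlocs:
                atoms = {}
                ok = True
                for idx, amap, names in ((1, map1, names1), (2, map2, names2)):
                    for role, name in names.items():
                        atom = _resolve(amap, name, alt, min_occupancy)
                        if atom is None:
                            ok = False
                            break
                        atoms[(idx, role)] = _record(atom)
                    if not ok:
                        break
                if not ok:
                    continue
                link = np.linalg.norm(atoms[(1, "O3'")].xyz - atoms[(2, "P")].xyz)
                if link > linkage_cutoff:
                    continue
                ref1 = ResidueRef(model_no, chain.name, r1.name, r1.seqid.num,
                                  _blank(r1.seqid.icode), atoms[(1, "C1'")].altloc)
                ref2 = ResidueRef(model_no, chain.name, r2.name, r2.seqid.num,
                                  _blank(r2.seqid.icode), atoms[(2, "C1'")].altloc)
                if alt:  # label the step with the expanded altloc id
                    ref1 = ResidueRef(ref1.model_no, ref1.chain_id, ref1.res_name,
                                      ref1.res_seq, ref1.ins_code,
                                      ref1.altloc or (alt if _has_alt(map1, names1, alt) else ""))
                    ref2 = ResidueRef(ref2.model_no, ref2.chain_id, ref2.res_name,
                                      ref2.res_seq, ref2.ins_code,
                                      ref2.altloc or (alt if _has_alt(map2, names2, alt) else ""))
                step = DinucleotideStep(first=ref1, second=ref2, atoms=atoms)
                step.step_name = step_name(step, pid, multi_model)
                steps.append(step)
    return steps


def _has_alt(amap, names, alt) -> bool:
    return any(alt in amap.get(name, {}) for name in names.values())


def step_name(step: DinucleotideStep, pdb_id: str, multi_model: bool = False) -> str:
    """Canonical step name: PDBID[-mmodel#]_chain_resname[.altloc]resnr[.inscode]_..."""
    head = pdb_id
    if multi_model:
        head += f"-m{step.first.model_no}"
    return f"{head}_{step.first.chain_id}_{step.first.label()}_{step.second.label()}"
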